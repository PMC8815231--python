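"""Clinicopathological association tests and germline/somatic position comparison.

Fisher's exact test is computed directly from the hypergeometric distribution
(two-sided p = sum of table probabilities no larger than the observed one,
with a small tolerance for floating-point ties) so its contract can be checked
against full table enumeration. The r x c chi-square and Kruskal-Wallis tests
delegate to scipy; an exact permutation Kruskal-Wallis is available for very
small samples where the chi-square approximation is unreliable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PositionSample",
    "fisher_exact_2x2",
    "chi_square_rxc",
    "kruskal_wallis",
    "compare_position_distributions",
    "contingency_from_labels",
]

_TIE_TOL = 1e-12


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table: ``(p_value, odds_ratio)``.

    p sums hypergeometric probabilities over all tables with the observed
    margins whose probability is <= the observed table's (within 1e-12, so
    equal-probability tables on the other tail are included). The odds ratio
    is the sample OR, with a Haldane half-count added to every cell when any
    cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be a 2x2 array of nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("empty margin in 2x2 table; p = 1")
        return 1.0, _odds_ratio(a, b, c, d)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _TIE_TOL) + _TIE_TOL].sum())
    return min(p, 1.0), _odds_ratio(a, b, c, d)


def _odds_ratio(a, b, c, d) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def chi_square_rxc(table) -> tuple[float, float, int]:
    """Pearson chi-square test of independence: ``(statistic, p_value, df)``.

    No continuity correction. Warns when any expected count is below 5
    (the chi-square approximation degrades there).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    stat, p, df, expected = stats.chi2_contingency(t, correction=False)
    if np.any(expected < 5):
        warnings.warn("expected count < 5 in chi-square table; "
                      "consider Fisher's exact test")
    return float(stat), float(p), int(df)


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with midrank tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n) if n > 1 else 1.0
    return h / tie_corr if tie_corr > 0 else 0.0


def kruskal_wallis(samples: Sequence[Sequence[float]],
                   exact: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups: ``(H, p_value)``.

    By default p comes from chi-square(k-1). With ``exact=True`` (allowed for
    total n <= 10) the p-value is computed by full enumeration of the group
    assignments, i.e. the permutation distribution of H.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    n = len(pooled)
    if exact:
        if n > 10:
            raise ValueError("exact enumeration limited to total n <= 10")
        h_obs = _kw_statistic(groups)
        sizes = [len(g) for g in groups]
        count = 0
        total = 0
        for perm in _group_assignments(pooled, sizes):
            total += 1
            if _kw_statistic(perm) >= h_obs - 1e-12:
                count += 1
        return float(h_obs), count / total
    if n < 5:
        warnings.warn("total n < 5: chi-square approximation is crude")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _group_assignments(pooled: np.ndarray, sizes: list[int]):
    """All partitions of pooled indices into ordered groups of given sizes."""
    idx = tuple(range(len(pooled)))

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in rec(rest, sizes_left[1:]):
                yield [np.array(combo)] + tail

    for assignment in rec(idx, sizes):
        yield [pooled[a] for a in assignment]


@dataclass
class PositionSample:
    """Protein positions of variants from one source (somatic or germline)."""

    source: str  # "somatic" | "germline"
    gene: str
    positions: list[int]
    protein_length: Optional[int] = None

    def __post_init__(self):
        if self.source not in ("somatic", "germline"):
            raise ValueError("source must be 'somatic' or 'germline'")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions must be >= 1")
        if self.protein_length is not None and any(
                p > self.protein_length for p in self.positions):
            raise ValueError("position beyond protein length")


def compare_position_distributions(somatic: PositionSample,
                                   germline: PositionSample,
                                   bins: int = 20) -> dict:
    """Compare somatic vs germline variant position distributions on one gene.

    Returns a report dict with the Kruskal-Wallis p-value, per-source
    histograms over shared bins, per-source medians, and the recurrent
    positions (observed >= 2 times within a source).
    """
    if somatic.gene != germline.gene:
        raise ValueError(
            f"gene mismatch: {somatic.gene!r} vs {germline.gene!r}")
    if not somatic.positions or not germline.positions:
        raise ValueError("both position lists must be non-empty")
    h, p = kruskal_wallis([somatic.positions, germline.positions])
    upper = max(somatic.protein_length or 0, germline.protein_length or 0,
                max(somatic.positions), max(germline.positions))
    edges = np.linspace(0.5, upper + 0.5, bins + 1)
    hist_som, _ = np.histogram(somatic.positions, bins=edges)
    hist_germ, _ = np.histogram(germline.positions, bins=edges)

    def recurrent(positions):
        vals, counts = np.unique(positions, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if c >= 2}

    return {
        "gene": somatic.gene,
        "kruskal_wallis_h": h,
        "p_value": p,
        "bin_edges": edges.tolist(),
        "histogram_somatic": hist_som.tolist(),
        "histogram_germline": hist_germ.tolist(),
        "median_somatic": float(np.median(somatic.positions)),
        "median_germline": float(np.median(germline.positions)),
        "recurrent_somatic": recurrent(somatic.positions),
        "recurrent_germline": recurrent(germline.positions),
    }


def contingency_from_labels(rows: Sequence, cols: Sequence) -> np.ndarray:
    """Cross-tabulate two categorical label vectors into a count table."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if len(rows) != len(cols):
        raise ValueError("label vectors must have equal length")
    r_levels = np.unique(rows)
    c_levels = np.unique(cols)
    table = np.zeros((len(r_levels), len(c_levels)), dtype=int)
    for i, rv in enumerate(r_levels):
        for j, cv in enumerate(c_levels):
            table[i, j] = int(((rows == rv) & (cols == cv)).sum())
    return table
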