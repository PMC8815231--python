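"""Gene-family mutation-burden tests.

Two complementary views of "is the family mutated above background":

* :func:`rank_compare_frequencies` — a two-sided Wilcoxon rank-sum comparing
  the family's per-gene alteration frequencies with all other genes, ignoring
  gene size.
* :func:`moderated_ks_burden` — a gene-size-aware set test. Genes are ranked
  by mutations per coding base; the family's rank positions are compared to
  the uniform reference by a Kolmogorov-Smirnov sup distance, and significance
  comes from random gene sets of the same size, optionally drawn from
  length-decile-matched bins so the null sets resemble the family in size
  *and* length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .mutations import GeneMutationProfile

__all__ = [
    "RankTestResult",
    "ModeratedKSResult",
    "rank_compare_frequencies",
    "moderated_ks_burden",
]

EXACT_THRESHOLD = 8  # exact rank-sum enumeration when both groups are this small


@dataclass
class RankTestResult:
    statistic: float  # Mann-Whitney U for the family group
    p_value: float
    n_family: int
    n_background: int
    method: str  # "exact" | "normal_approx"


def rank_compare_frequencies(family_freqs: Sequence[float],
                             other_freqs: Sequence[float]) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) on alteration frequencies.

    Midranks handle ties; the normal approximation uses a continuity
    correction. Exact enumeration is used when both groups have at most
    ``EXACT_THRESHOLD`` members and there are no ties (the exact distribution
    assumes distinct values).
    """
    x = np.asarray(family_freqs, dtype=float)
    y = np.asarray(other_freqs, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both frequency lists must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # full ties: U at its null expectation, no evidence either way
        return RankTestResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                              n_family=len(x), n_background=len(y),
                              method="normal_approx")
    if len(x) <= EXACT_THRESHOLD and len(y) <= EXACT_THRESHOLD and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "normal_approx"
    return RankTestResult(statistic=float(res.statistic),
                          p_value=float(min(res.pvalue, 1.0)),
                          n_family=len(x), n_background=len(y), method=method)


@dataclass
class ModeratedKSResult:
    ks_statistic: float  # in [0, 1]
    p_value: float  # >= 1/(n_permutations+1)
    n_permutations: int
    direction: str  # "enriched" | "depleted"
    seed: Optional[int]


def _rank_genes(profiles: Sequence[GeneMutationProfile]) -> dict[str, int]:
    """1-based ranks, descending by mutations per coding base; ties broken by
    gene symbol so the ranking is deterministic."""
    ordered = sorted(profiles, key=lambda p: (-p.normalized_rate, p.gene))
    return {p.gene: i + 1 for i, p in enumerate(ordered)}


def ks_rank_statistic(ranks: np.ndarray, n_genes: int) -> float:
    """Sup distance between the family's rank positions and uniform spacing.

    For sorted family ranks r_1 < ... < r_k among N genes, the statistic is
    ``max_j | j/k - r_j/N |``: zero when the family is evenly spread through
    the ranking (e.g. family = all genes) and approaching 1 when the family
    occupies a narrow block at one extreme.
    """
    r = np.sort(np.asarray(ranks, dtype=float))
    k = len(r)
    j = np.arange(1, k + 1)
    return float(np.abs(j / k - r / n_genes).max())


def _null_rank_draws(rank_values: np.ndarray, lengths: np.ndarray,
                     family_idx: np.ndarray, n_permutations: int,
                     length_matched: bool, rng) -> np.ndarray:
    """(n_permutations, k) matrix of null gene-set ranks.

    Length-matched draws replace each family gene by a random gene from the
    same coding-length decile; unmatched draws are uniform size-k sets.
    """
    N = len(rank_values)
    k = len(family_idx)
    if not length_matched:
        u = rng.random((n_permutations, N))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        return rank_values[idx]
    # decile bins over all gene lengths
    edges = np.quantile(lengths, np.linspace(0, 1, 11))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, lengths, side="right") - 1, 0, len(edges) - 2)
    draws = []
    for b in np.unique(bins[family_idx]):
        members = np.nonzero(bins == b)[0]
        need = int((bins[family_idx] == b).sum())
        if need > len(members):  # degenerate binning; fall back to full pool
            members = np.arange(N)
        u = rng.random((n_permutations, len(members)))
        idx = np.argpartition(u, need - 1, axis=1)[:, :need]
        draws.append(rank_values[members[idx]])
    return np.concatenate(draws, axis=1)


def moderated_ks_burden(profiles: Sequence[GeneMutationProfile],
                        family: Iterable[str], n_permutations: int = 1000,
                        length_matched: bool = True,
                        seed: Optional[int] = None) -> ModeratedKSResult:
    """Gene-set burden test on the mutations-per-base ranking.

    ``p_value`` is the add-one permutation estimate
    ``(1 + #{null D >= observed D}) / (n_permutations + 1)`` over random gene
    sets of the family's size. ``direction`` is ``enriched`` when the family's
    mean rank is better (smaller) than the null sets' average mean rank.
    """
    family = sorted(set(family))
    if len(family) < 2:
        raise ValueError("family must contain at least 2 genes")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    by_gene = {p.gene: p for p in profiles}
    missing = [g for g in family if g not in by_gene]
    if missing:
        raise ValueError(f"family gene(s) missing a profile: {missing}")

    ranks_map = _rank_genes(profiles)
    genes = sorted(ranks_map)  # deterministic gene ordering
    rank_values = np.array([ranks_map[g] for g in genes], dtype=float)
    lengths = np.array([by_gene[g].coding_length for g in genes], dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    family_idx = np.array([gene_pos[g] for g in family])

    N = len(genes)
    observed = ks_rank_statistic(rank_values[family_idx], N)

    rng = np.random.default_rng(seed)
    null_ranks = _null_rank_draws(rank_values, lengths, family_idx,
                                  n_permutations, length_matched, rng)
    null_sorted = np.sort(null_ranks, axis=1)
    k = len(family_idx)
    j = np.arange(1, k + 1)
    null_stats = np.abs(j / k - null_sorted / N).max(axis=1)

    exceed = int((null_stats >= observed - 1e-12).sum())
    p = (1 + exceed) / (n_permutations + 1)
    family_mean_rank = float(rank_values[family_idx].mean())
    null_mean_rank = float(null_ranks.mean())
    direction = "enriched" if family_mean_rank < null_mean_rank else "depleted"
    return ModeratedKSResult(ks_statistic=observed, p_value=p,
                             n_permutations=n_permutations,
                             direction=direction, seed=seed)
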