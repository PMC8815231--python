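"""Gene-set combination survival scan with a mutation-count-matched null.

The scan enumerates subsets of 2-3 expressed family genes, marks each tumor
by whether it carries a qualifying mutation in any subset gene, and tests
mutated-vs-wildtype overall survival by log-rank. Significance is judged
against an empirical background: random gene sets drawn genome-wide until
their accumulated mutation count matches the candidate's observed count
within a tolerance, scored by exactly the same indicator / prevalence /
log-rank procedure. Candidate p-values are converted to q-values by plugging
the empirical null CDF into a Benjamini-Hochberg step-up sweep.

Because the null sets are matched on *mutation count*, the scan automatically
accounts for gene size and cohort mutation rate: a long gene in a hypermutated
cohort needs a much stronger survival separation to beat its background.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientBackgroundError
from .mutations import (GeneMutationProfile, MutationClass, MutationMatrix,
                        build_mutation_matrix, gene_profiles)
from .survival import PrecomputedLogRank, km_estimate, km_median

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationConfig",
    "Candidate",
    "CombinationResult",
    "BackgroundDraw",
    "ScanResult",
    "eligible_genes",
    "enumerate_candidates",
    "sample_background",
    "score_combinations",
    "inclusion_frequencies",
    "run_combination_scan",
]


@dataclass
class CombinationConfig:
    """Thresholds and sampling parameters of one combination scan.

    ``expression_threshold`` gates family genes on mean expression (RSEM
    scale, strict inequality). ``prevalence_threshold`` keeps subsets mutated
    in at least that fraction of the cohort. ``mutation_count_tolerance`` is
    the +/- window for matching a background draw's accumulated mutation
    count to a candidate's observed count.
    """

    subset_sizes: tuple[int, ...] = (2, 3)
    expression_threshold: float = 200.0
    prevalence_threshold: float = 0.05
    mutation_count_tolerance: int = 5
    n_background: int = 1000
    q_threshold: float = 0.05
    exclude_significant_subsets: bool = True
    exclude_family_from_background: bool = True
    match_family_total: bool = False  # match background to the family-wide total
    classes: frozenset = frozenset({MutationClass.MISSENSE, MutationClass.TRUNCATION})
    seed: int = 0

    def validate(self) -> None:
        if not self.subset_sizes or not set(self.subset_sizes) <= {2, 3}:
            raise ValueError("subset_sizes must be a non-empty subset of {2, 3}")
        if self.expression_threshold < 0 or self.prevalence_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_background < 100:
            raise ValueError("n_background must be >= 100")
        if self.mutation_count_tolerance < 0:
            raise ValueError("mutation_count_tolerance must be >= 0")


@dataclass(frozen=True)
class Candidate:
    genes: tuple[str, ...]
    indicator: np.ndarray  # per-sample 0/1, aligned to the matrix sample order
    n_mutated: int
    prevalence: float


@dataclass
class CombinationResult:
    genes: tuple[str, ...]
    n_mutated: int
    prevalence: float
    logrank_p: float
    direction: str  # "longer_OS" | "shorter_OS"
    q_value: float


@dataclass
class BackgroundDraw:
    genes: tuple[str, ...]
    total_mutations: int
    logrank_p: Optional[float]  # None when the prevalence filter failed


def eligible_genes(expression: Mapping[str, float], family: Iterable[str],
                   config: CombinationConfig) -> list[str]:
    """Family genes with mean expression strictly above the threshold.

    Family genes without an expression entry are excluded with a warning;
    an empty result raises, since the scan would be vacuous.
    """
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    family = sorted(set(family))
    missing = [g for g in family if g not in expression]
    if missing:
        logger.warning("family gene(s) without expression entry excluded: %s",
                       missing)
    out = [g for g in family
           if g in expression and expression[g] > config.expression_threshold]
    if not out:
        raise ValueError(
            "no family genes pass the expression threshold "
            f"({config.expression_threshold}); review the threshold")
    return out


def enumerate_candidates(eligible: Sequence[str], matrix: MutationMatrix,
                         config: CombinationConfig, size: int,
                         excluded_subsets: Iterable[frozenset] = ()) -> list[Candidate]:
    """All size-``size`` subsets of eligible genes passing the prevalence rule.

    ``excluded_subsets`` drops any subset containing one of the given smaller
    subsets (the already-significant-pair exclusion).
    """
    eligible = sorted(set(eligible))
    missing = set(eligible) - set(matrix.genes)
    if missing:
        raise ValueError(f"eligible gene(s) absent from matrix: {sorted(missing)}")
    excluded = [frozenset(s) for s in excluded_subsets]
    n = len(matrix.samples)
    data = matrix.data[eligible].to_numpy()
    col = {g: j for j, g in enumerate(eligible)}
    out = []
    for combo in itertools.combinations(eligible, size):
        if any(sub <= set(combo) for sub in excluded):
            continue
        indicator = (data[:, [col[g] for g in combo]].sum(axis=1) > 0).astype(np.int8)
        n_mut = int(indicator.sum())
        prevalence = n_mut / n
        if prevalence >= config.prevalence_threshold:
            out.append(Candidate(genes=combo, indicator=indicator,
                                 n_mutated=n_mut, prevalence=prevalence))
    return out


def sample_background(profiles: Sequence[GeneMutationProfile], target_mutations: int,
                      tolerance: int, rng: np.random.Generator,
                      max_restarts: int = 1000) -> BackgroundDraw:
    """One random gene set whose accumulated mutation count lands in
    ``[target - tolerance, target + tolerance]``.

    Genes are drawn uniformly without replacement; a gene whose count would
    overshoot the window is discarded and the next one tried. If a pass over
    all genes cannot land in the window the draw restarts with a fresh
    shuffle, up to ``max_restarts`` (then raises — e.g. the target is smaller
    than every single gene's count).
    """
    if target_mutations <= 0:
        raise ValueError("target_mutations must be > 0")
    genes = np.array([p.gene for p in profiles])
    counts = np.array([p.n_mutations for p in profiles])
    lo, hi = target_mutations - tolerance, target_mutations + tolerance
    for _ in range(max_restarts):
        order = rng.permutation(len(genes))
        total = 0
        chosen = []
        for idx in order:
            c = counts[idx]
            if total + c > hi:
                continue  # overshoot: discard this gene, try the next
            total += c
            chosen.append(idx)
            if total >= lo:
                return BackgroundDraw(genes=tuple(genes[chosen]),
                                      total_mutations=int(total), logrank_p=None)
        # fell short of the window after exhausting the pool; redraw
    raise InsufficientBackgroundError(
        f"could not reach mutation-count window [{lo}, {hi}] "
        f"in {max_restarts} attempts")


def _direction(times, events, indicator) -> str:
    """longer_OS vs shorter_OS from KM median difference, falling back to the
    observed-vs-expected event balance when a group median is undefined."""
    mut = indicator.astype(bool)
    med_mut = km_median(km_estimate((times[mut], events[mut])))
    med_wt = km_median(km_estimate((times[~mut], events[~mut])))
    if np.isfinite(med_mut) or np.isfinite(med_wt):
        if med_mut != med_wt:
            return "longer_OS" if med_mut > med_wt else "shorter_OS"
    pre = PrecomputedLogRank(times, events)
    _, O1, E1, _ = pre.statistics(indicator)
    return "longer_OS" if O1 <= E1 else "shorter_OS"


def score_combinations(candidates: Sequence[Candidate], clinical: pd.DataFrame,
                       profiles: Sequence[GeneMutationProfile],
                       matrix: MutationMatrix, config: CombinationConfig,
                       rng: Optional[np.random.Generator] = None,
                       family: Iterable[str] = ()) -> list[CombinationResult]:
    """Log-rank score + empirical q-value for each candidate subset.

    Backgrounds are matched on the candidate's total mutation count (sum of
    the member genes' mutation events): candidates sharing a target share one
    background sample of ``config.n_background`` draws. Draws failing the
    prevalence rule are excluded from the null denominator; fewer than 10
    valid draws for a target raises. With ``config.match_family_total`` every
    candidate is instead matched to the family-wide mutation total.
    """
    if not candidates:
        return []
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clinical = clinical.loc[matrix.samples]
    times = clinical["os_months"].to_numpy(float)
    events = clinical["os_event"].to_numpy(int)
    pre = PrecomputedLogRank(times, events)

    by_gene = {p.gene: p for p in profiles}
    family = set(family)
    pool = [p for p in profiles
            if not (config.exclude_family_from_background and
                    (p.in_family or p.gene in family))]
    pool = [p for p in pool if p.n_mutations > 0]
    family_total = sum(p.n_mutations for p in profiles if p.in_family or p.gene in family)

    def target_of(cand: Candidate) -> int:
        if config.match_family_total:
            return family_total
        return sum(by_gene[g].n_mutations for g in cand.genes)

    targets = sorted({target_of(c) for c in candidates})
    null_ps: dict[int, np.ndarray] = {}
    n_samples = len(matrix.samples)
    for target in targets:
        ps = []
        for _ in range(config.n_background):
            draw = sample_background(pool, target, config.mutation_count_tolerance, rng)
            indicator = matrix.set_indicator(draw.genes)
            if indicator.sum() / n_samples < config.prevalence_threshold:
                continue  # excluded from the null denominator
            ps.append(pre.p_value(indicator))
        if len(ps) < 10:
            raise InsufficientBackgroundError(
                f"only {len(ps)} of {config.n_background} background draws for "
                f"target {target} passed the prevalence filter")
        null_ps[target] = np.sort(np.array(ps))

    obs_p = np.array([pre.p_value(c.indicator) for c in candidates])
    f0 = np.empty(len(candidates))
    for i, cand in enumerate(candidates):
        null = null_ps[target_of(cand)]
        f0[i] = (1 + np.searchsorted(null, obs_p[i] + 1e-15, side="right")) / (len(null) + 1)

    # empirical-null plug-in + BH step-up monotonization
    m = len(candidates)
    order = np.argsort(obs_p, kind="stable")
    q_sorted = f0[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted

    results = []
    for i, cand in enumerate(candidates):
        results.append(CombinationResult(
            genes=cand.genes, n_mutated=cand.n_mutated,
            prevalence=cand.prevalence, logrank_p=float(obs_p[i]),
            direction=_direction(times, events, cand.indicator),
            q_value=float(q[i]),
        ))
    return results


def inclusion_frequencies(results: Sequence[CombinationResult],
                          q_threshold: float = 0.05) -> dict[str, dict[str, int]]:
    """Per-gene counts of membership in significant combinations, by direction."""
    out = {"longer_OS": {}, "shorter_OS": {}}
    for r in results:
        if r.q_value <= q_threshold:
            for g in r.genes:
                out[r.direction][g] = out[r.direction].get(g, 0) + 1
    return out


@dataclass
class ScanResult:
    results: list[CombinationResult]
    inclusion: dict[str, dict[str, int]]
    metadata: dict = field(default_factory=dict)

    def significant(self, q_threshold: Optional[float] = None) -> list[CombinationResult]:
        qt = self.metadata.get("q_threshold", 0.05) if q_threshold is None else q_threshold
        return [r for r in self.results if r.q_value <= qt]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "genes": ",".join(r.genes), "n_mutated": r.n_mutated,
            "prevalence": r.prevalence, "logrank_p": r.logrank_p,
            "direction": r.direction, "q_value": r.q_value,
        } for r in self.results])


def run_combination_scan(records, clinical: pd.DataFrame,
                         expression: Mapping[str, float],
                         gene_lengths: Mapping[str, int],
                         family: Iterable[str],
                         config: CombinationConfig) -> ScanResult:
    """End-to-end scan: matrix construction, staged enumeration, scoring.

    Sizes are processed in increasing order so that size-2 subsets already
    significant at ``q_threshold`` can be excluded from the size-3 stage
    (when ``exclude_significant_subsets`` is on). q-values are computed
    within each size stratum.
    """
    config.validate()
    family = sorted(set(family))
    samples = list(clinical.index)
    matrix = build_mutation_matrix(records, samples, sorted(gene_lengths),
                                   config.classes)
    profiles = gene_profiles(records, gene_lengths, family, classes=config.classes)
    eligible = eligible_genes(expression, family, config)

    rng = np.random.default_rng(config.seed)
    all_results: list[CombinationResult] = []
    significant_smaller: list[frozenset] = []
    for size in sorted(config.subset_sizes):
        excluded = significant_smaller if (
            size == 3 and config.exclude_significant_subsets) else []
        cands = enumerate_candidates(eligible, matrix, config, size,
                                     excluded_subsets=excluded)
        res = score_combinations(cands, clinical, profiles, matrix, config,
                                 rng=rng, family=family)
        all_results.extend(res)
        significant_smaller.extend(
            frozenset(r.genes) for r in res if r.q_value <= config.q_threshold)

    inclusion = inclusion_frequencies(all_results, config.q_threshold)
    metadata = {
        "n_samples": len(samples),
        "n_candidates": len(all_results),
        "eligible_genes": eligible,
        "subset_sizes": sorted(config.subset_sizes),
        "expression_threshold": config.expression_threshold,
        "prevalence_threshold": config.prevalence_threshold,
        "mutation_count_tolerance": config.mutation_count_tolerance,
        "n_background": config.n_background,
        "q_threshold": config.q_threshold,
        "classes": sorted(c.value for c in config.classes),
        "seed": config.seed,
    }
    return ScanResult(results=all_results, inclusion=inclusion, metadata=metadata)
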