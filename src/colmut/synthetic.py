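"""Synthetic tumor-cohort generator.

Emulates the statistical structure of a TCGA-style stomach adenocarcinoma
cohort: two microsatellite classes with very different mutation burdens
(MSS low, MSIH high), gene-length-proportional placement of somatic
mutations, missense/truncating variant labels, exponential survival under
proportional hazards with optional planted effect gene sets, independent
exponential right-censoring, and RSEM-scale per-gene mean expression.

Every generated cohort carries a :class:`SyntheticTruth` record of the
planted parameters so that downstream estimators can be tested for recovery.
Output tables mirror the real readers (MAF-dialect TSV, clinical TSV) so the
pipeline is exercised through its I/O layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_germline_variants",
    "simulate_two_group_survival",
    "write_cohort",
]

TRUNCATING_LABELS = (
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Mutation rates are expected mutations per megabase of coding sequence per
    sample; hazard rates are per month. ``effect_sets`` is a list of
    ``(gene_set, log_hazard_ratio)`` pairs: a sample whose mutations hit any
    gene of a set multiplies its death hazard by ``exp(log_hr)``.
    ``family_rate_multiplier`` inflates the per-base mutation rate of family
    genes relative to background (1.0 = null). Family genes are named
    ``FAM001..``, background genes ``GEN001..``.
    """

    n_samples: int = 300
    frac_msih: float = 0.3
    n_genes: int = 200
    n_family_genes: int = 40
    gene_length_range: tuple[int, int] = (1000, 9000)
    mut_rate_mss: float = 3.0
    mut_rate_msih: float = 30.0
    frac_truncation: float = 0.3
    family_rate_multiplier: float = 1.0
    effect_sets: list[tuple[frozenset, float]] = field(default_factory=list)
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.015
    expression_range: tuple[float, float] = (0.0, 2000.0)
    hotspot: Optional[tuple[str, int, float]] = None  # (gene, protein pos, weight)
    seed: int = 0

    def family_gene_names(self) -> list[str]:
        return [f"FAM{i + 1:03d}" for i in range(self.n_family_genes)]

    def gene_names(self) -> list[str]:
        fam = self.family_gene_names()
        bg = [f"GEN{i + 1:03d}" for i in range(self.n_genes - self.n_family_genes)]
        return fam + bg

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not 0.0 <= self.frac_msih <= 1.0:
            raise ConfigError("frac_msih must lie in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0 <= self.n_family_genes <= self.n_genes:
            raise ConfigError("n_family_genes must lie in [0, n_genes]")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError("gene_length_range must be positive and ordered")
        if self.mut_rate_mss <= 0 or self.mut_rate_msih <= 0:
            raise ConfigError("mut_rate_mss and mut_rate_msih must be > 0")
        if self.mut_rate_msih < self.mut_rate_mss:
            raise ConfigError("mut_rate_msih must be >= mut_rate_mss")
        if not 0.0 <= self.frac_truncation <= 1.0:
            raise ConfigError("frac_truncation must lie in [0, 1]")
        if self.family_rate_multiplier <= 0:
            raise ConfigError("family_rate_multiplier must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censoring_rate <= 0:
            raise ConfigError("censoring_rate must be > 0")
        elo, ehi = self.expression_range
        if elo < 0 or ehi < elo:
            raise ConfigError("expression_range must be nonnegative and ordered")
        fam = set(self.family_gene_names())
        for genes, _ in self.effect_sets:
            if not set(genes) <= fam:
                raise ConfigError(
                    f"effect_sets genes must be family genes; offending set: {sorted(genes)}")
        if self.hotspot is not None:
            gene, pos, weight = self.hotspot
            if gene not in set(self.gene_names()):
                raise ConfigError(f"hotspot gene {gene!r} not among simulated genes")
            if not 0.0 <= weight <= 1.0:
                raise ConfigError("hotspot weight must lie in [0, 1]")
            if pos < 1:
                raise ConfigError("hotspot position must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated cohort, for recovery tests."""

    msi_status: dict  # sample -> "MSS" | "MSIH"
    hazard_multiplier: dict  # sample -> exp(sum of active log-HRs)
    effect_sets: list  # [(sorted gene list, log_hr)]
    gene_lengths: dict  # gene -> coding bases
    in_family: dict  # gene -> bool

    def to_json(self) -> str:
        def _plain(o):
            if isinstance(o, (np.integer, np.bool_)):
                return o.item()
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        payload = asdict(self)
        payload["effect_sets"] = [[sorted(g), lh] for g, lh in self.effect_sets]
        return json.dumps(payload, indent=1, sort_keys=True, default=_plain)


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort.

    Returns ``(mutations, clinical, expression, gene_annotation, truth)`` —
    four DataFrames in the on-disk column layout plus the truth record.

    Per sample, the mutation count is Poisson with mean
    ``rate_class * effective_coding_length / 1e6``; each mutation lands on a
    gene with probability proportional to its (family-multiplied) coding
    length, is truncating with probability ``frac_truncation`` (else
    missense), and gets a protein position uniform on ``1..length//3``.
    Survival is exponential with rate ``baseline_hazard * exp(sum of active
    log-HRs)``, censored by an independent exponential. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = np.array(config.gene_names())
    in_family = np.arange(config.n_genes) < config.n_family_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    # protein coordinates: coding length / 3, floored, at least 1 residue
    prot_len = np.maximum(lengths // 3, 1)

    weights = lengths.astype(float)
    weights[in_family] *= config.family_rate_multiplier
    probs = weights / weights.sum()

    samples = np.array([f"S{i + 1:04d}" for i in range(config.n_samples)])
    is_msih = rng.random(config.n_samples) < config.frac_msih
    rates = np.where(is_msih, config.mut_rate_msih, config.mut_rate_mss)
    lam = rates * weights.sum() / 1e6
    counts = rng.poisson(lam)
    total = int(counts.sum())

    gene_idx = rng.choice(config.n_genes, size=total, p=probs)
    sample_idx = np.repeat(np.arange(config.n_samples), counts)
    is_trunc = rng.random(total) < config.frac_truncation
    var_class = np.where(
        is_trunc,
        rng.choice(TRUNCATING_LABELS, size=total),
        "Missense_Mutation",
    )
    plen = prot_len[gene_idx]
    positions = rng.integers(1, plen + 1)
    if config.hotspot is not None:
        hgene, hpos, hweight = config.hotspot
        gi = int(np.nonzero(genes == hgene)[0][0])
        if hpos > prot_len[gi]:
            raise ConfigError(
                f"hotspot position {hpos} beyond protein length {prot_len[gi]}")
        on_gene = gene_idx == gi
        hot = on_gene & (rng.random(total) < hweight)
        positions = np.where(hot, hpos, positions)

    mutations = pd.DataFrame({
        "Hugo_Symbol": genes[gene_idx],
        "Tumor_Sample_Barcode": samples[sample_idx],
        "Variant_Classification": var_class,
        "Protein_position": [f"{p}/{q}" for p, q in zip(positions, plen)],
    })

    # planted survival effects: any mutation (any class) in an effect set's genes
    log_mult = np.zeros(config.n_samples)
    gene_of = pd.Index(genes)
    for genes_in_set, log_hr in config.effect_sets:
        idxs = gene_of.get_indexer(sorted(genes_in_set))
        hit = np.zeros(config.n_samples, dtype=bool)
        member = np.isin(gene_idx, idxs)
        hit[np.unique(sample_idx[member])] = True
        log_mult += np.where(hit, log_hr, 0.0)
    hazard = config.baseline_hazard * np.exp(log_mult)

    latent_t = rng.exponential(1.0 / hazard)
    censor_t = rng.exponential(1.0 / config.censoring_rate, size=config.n_samples)
    observed = np.minimum(latent_t, censor_t)
    # month-resolution follow-up, as clinical tables record it; ceil keeps times > 0
    os_months = np.ceil(observed)
    os_event = (latent_t <= censor_t).astype(int)

    clinical = pd.DataFrame({
        "sample": samples,
        "os_months": os_months,
        "os_event": os_event,
        "msi_status": np.where(is_msih, "MSIH", "MSS"),
        "age": np.clip(np.round(rng.normal(66, 10, config.n_samples)), 30, 90).astype(int),
        "stage": rng.choice([1, 2, 3, 4], size=config.n_samples, p=[0.1, 0.3, 0.35, 0.25]),
    })

    elo, ehi = config.expression_range
    expression = pd.DataFrame({
        "gene": genes,
        "mean_rsem": np.round(rng.uniform(elo, ehi, config.n_genes), 2),
    })

    gene_annotation = pd.DataFrame({
        "gene": genes,
        "coding_length": lengths,
        "in_family": in_family.astype(int),
    })

    truth = SyntheticTruth(
        msi_status=dict(zip(samples, np.where(is_msih, "MSIH", "MSS"))),
        hazard_multiplier=dict(zip(samples, np.exp(log_mult))),
        effect_sets=[(sorted(g), lh) for g, lh in config.effect_sets],
        gene_lengths=dict(zip(genes, lengths.astype(int))),
        in_family=dict(zip(genes, in_family.astype(bool))),
    )
    return mutations, clinical, expression, gene_annotation, truth


def simulate_germline_variants(gene_length: int, n_variants: int,
                               hotspot_position: Optional[int] = None,
                               hotspot_weight: float = 0.0,
                               seed: Optional[int] = None) -> list[int]:
    """Draw germline variant protein positions for one gene.

    Positions are uniform on ``1..gene_length//3``; with a hotspot, that
    residue is drawn with probability ``hotspot_weight`` (plus its share of
    the uniform remainder), emulating the recurrent founder variants seen in
    collagenopathy databases.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    plen = max(gene_length // 3, 1)
    if hotspot_position is not None and not 1 <= hotspot_position <= plen:
        raise ValueError(
            f"hotspot position {hotspot_position} outside protein (1..{plen})")
    if not 0.0 <= hotspot_weight <= 1.0:
        raise ValueError("hotspot_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = rng.integers(1, plen + 1, size=n_variants)
    if hotspot_position is not None and hotspot_weight > 0:
        hot = rng.random(n_variants) < hotspot_weight
        positions = np.where(hot, hotspot_position, positions)
    return [int(p) for p in positions]


def simulate_two_group_survival(n: int, log_hr: float, frac_exposed: float = 0.5,
                                baseline_hazard: float = 0.02,
                                censoring_rate: float = 0.01,
                                round_months: bool = False,
                                seed: Optional[int] = None):
    """Minimal two-arm proportional-hazards dataset for estimator checks.

    Returns ``(times, events, exposed)`` numpy arrays. Exposure is Bernoulli;
    the exposed arm's hazard is ``baseline_hazard * exp(log_hr)``.
    """
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < frac_exposed).astype(float)
    hazard = baseline_hazard * np.exp(log_hr * x)
    latent = rng.exponential(1.0 / hazard)
    censor = rng.exponential(1.0 / censoring_rate, size=n)
    times = np.minimum(latent, censor)
    if round_months:
        times = np.ceil(times)
    events = (latent <= censor).astype(int)
    return times, events, x


def write_cohort(outdir, mutations: pd.DataFrame, clinical: pd.DataFrame,
                 expression: pd.DataFrame, gene_annotation: pd.DataFrame,
                 truth: Optional[SyntheticTruth] = None) -> dict:
    """Write cohort tables as TSV (+ truth JSON); returns the path map.

    Byte-stable for fixed inputs, so identical seeds yield identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": outdir / "mutations.maf",
        "clinical": outdir / "clinical.tsv",
        "expression": outdir / "expression.tsv",
        "genes": outdir / "genes.tsv",
    }
    mutations.to_csv(paths["maf"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.1f")
    expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.2f")
    gene_annotation.to_csv(paths["genes"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths
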