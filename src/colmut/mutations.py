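"""MAF-style mutation I/O, variant classification, and indicator matrices.

The variant-class vocabulary follows the MC3 MAF dialect. A mutation is
*truncating* when its annotated consequence is predicted to yield a shorter
protein or no protein product at all: nonsense, frameshift (either
direction), splice-affecting, nonstop, and translation-start variants.
In-frame indels keep the reading frame and are not truncating; silent,
UTR, intronic, RNA and any unrecognized classes fall into ``other``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "MutationClass",
    "MutationRecord",
    "MutationMatrix",
    "GeneMutationProfile",
    "classify_mutation",
    "read_maf",
    "read_clinical",
    "read_expression",
    "read_gene_annotation",
    "build_mutation_matrix",
    "alteration_frequency",
    "gene_profiles",
    "records_from_frame",
]

REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

_TRUNCATING = frozenset({
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Nonstop_Mutation",
    "Translation_Start_Site",
})
_MISSENSE = frozenset({"Missense_Mutation"})
_KNOWN_OTHER = frozenset({
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
    "In_Frame_Del", "In_Frame_Ins", "RNA", "IGR", "De_novo_Start_InFrame",
    "De_novo_Start_OutOfFrame",
})
_warned_classes: set[str] = set()


class MutationClass(str, Enum):
    MISSENSE = "missense"
    TRUNCATION = "truncation"
    OTHER = "other"


def classify_mutation(variant_class: str) -> MutationClass:
    """Map a MAF ``Variant_Classification`` string to a coarse class.

    Unknown strings map to ``other`` (logged once per distinct string).
    """
    if not variant_class:
        raise ValueError("variant_class must be a non-empty string")
    if variant_class in _TRUNCATING:
        return MutationClass.TRUNCATION
    if variant_class in _MISSENSE:
        return MutationClass.MISSENSE
    if variant_class not in _KNOWN_OTHER and variant_class not in _warned_classes:
        _warned_classes.add(variant_class)
        logger.warning("unrecognized Variant_Classification %r mapped to 'other'",
                       variant_class)
    return MutationClass.OTHER


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call."""

    gene: str
    sample: str
    variant_class: str
    protein_position: Optional[int] = None

    def __post_init__(self):
        if not self.gene or not self.sample:
            raise ValueError("gene and sample must be non-empty")
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError("protein_position must be >= 1 when present")

    @property
    def mutation_class(self) -> MutationClass:
        return classify_mutation(self.variant_class)


_POSITION_RE = re.compile(r"^\s*(\d+)")
_HGVSP_RE = re.compile(r"p\.[A-Za-z*]{1,3}?(\d+)")


def _parse_position(pos_token, hgvsp_token) -> Optional[int]:
    """Protein position from a numeric/slash token ('2029/2944') or HGVSp."""
    for token, rx in ((pos_token, _POSITION_RE), (hgvsp_token, _HGVSP_RE)):
        if token is None or (isinstance(token, float) and np.isnan(token)):
            continue
        m = rx.search(str(token))
        if m:
            p = int(m.group(1))
            if p >= 1:
                return p
    return None


def read_maf(path, allowed_samples: Optional[Iterable[str]] = None,
             normalize_barcodes: bool = False) -> list[MutationRecord]:
    """Read a MAF-dialect TSV into a list of :class:`MutationRecord`.

    Gzip is handled transparently. ``Protein_position`` is parsed from a
    numeric or slash-delimited column when present, falling back to an
    HGVSp-style token (``HGVSp_Short``); it is absent when unparseable.
    ``normalize_barcodes`` truncates sample barcodes to the 15-character
    TCGA sample prefix; by default barcodes are matched verbatim.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         compression="infer", low_memory=False)
    except pd.errors.EmptyDataError:
        logger.warning("MAF file %s is empty", path)
        return []
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF file missing required column(s): {missing}")
    if df.empty:
        logger.warning("MAF file %s has a header but no data rows", path)
        return []

    barcodes = df["Tumor_Sample_Barcode"].astype(str)
    if normalize_barcodes:
        barcodes = barcodes.str.slice(0, 15)
    pos_col = df["Protein_position"] if "Protein_position" in df.columns else None
    hgvsp_col = df["HGVSp_Short"] if "HGVSp_Short" in df.columns else None

    if allowed_samples is not None:
        allowed_samples = set(allowed_samples)

    records = []
    for i in range(len(df)):
        sample = barcodes.iat[i]
        if allowed_samples is not None and sample not in allowed_samples:
            continue
        records.append(MutationRecord(
            gene=df["Hugo_Symbol"].iat[i],
            sample=sample,
            variant_class=df["Variant_Classification"].iat[i],
            protein_position=_parse_position(
                pos_col.iat[i] if pos_col is not None else None,
                hgvsp_col.iat[i] if hgvsp_col is not None else None,
            ),
        ))
    return records


def records_from_frame(mutations: pd.DataFrame) -> list[MutationRecord]:
    """Build records from an in-memory mutation table (generator output)."""
    return [
        MutationRecord(
            gene=row.Hugo_Symbol,
            sample=row.Tumor_Sample_Barcode,
            variant_class=row.Variant_Classification,
            protein_position=_parse_position(getattr(row, "Protein_position", None), None),
        )
        for row in mutations.itertuples(index=False)
    ]


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV -> DataFrame indexed by sample (os_months, os_event, ...)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing column(s): {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise DataError("duplicate sample identifiers in clinical table")
    return df.set_index("sample")


def read_expression(path) -> pd.Series:
    """Expression TSV (gene, mean_rsem) -> Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "mean_rsem"} - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing column(s): {sorted(missing)}")
    return df.set_index("gene")["mean_rsem"].astype(float)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV (gene, coding_length, in_family) -> DataFrame."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "coding_length"} - set(df.columns)
    if missing:
        raise FormatError(f"gene annotation missing column(s): {sorted(missing)}")
    if (df["coding_length"] <= 0).any():
        raise DataError("gene coding lengths must be strictly positive")
    if "in_family" not in df.columns:
        df["in_family"] = 0
    return df.set_index("gene")


@dataclass
class MutationMatrix:
    """Binary sample x gene indicator: 1 iff the sample carries >= 1 qualifying
    mutation in the gene (qualifying = class in ``class_filter``)."""

    data: pd.DataFrame  # int8, index = samples, columns = genes
    class_filter: frozenset

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def _columns(self):
        # cached numpy view: set_indicator is called tens of thousands of
        # times per combination scan, where pandas label indexing dominates
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = (self.data.to_numpy(),
                     {g: j for j, g in enumerate(self.data.columns)})
            object.__setattr__(self, "_cache", cache)
        return cache

    def set_indicator(self, genes: Sequence[str]) -> np.ndarray:
        """Per-sample 0/1: at least one qualifying mutation in any listed gene."""
        arr, col = self._columns()
        idx = [col[g] for g in genes]
        return (arr[:, idx].sum(axis=1) > 0).astype(np.int8)


def _as_class_set(classes) -> frozenset:
    out = set()
    for c in classes:
        out.add(MutationClass(c) if not isinstance(c, MutationClass) else c)
    return frozenset(out)


def build_mutation_matrix(records: Sequence[MutationRecord], samples: Sequence[str],
                          genes: Sequence[str], classes) -> MutationMatrix:
    """Binary indicator matrix over the given sample and gene orderings.

    Samples with no qualifying records appear as all-zero rows. Records
    referencing samples outside ``samples`` are ignored (count logged);
    records for genes outside ``genes`` are likewise ignored.
    """
    samples = list(samples)
    genes = list(genes)
    if not samples or not genes:
        raise ValueError("samples and genes must be non-empty")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample identifiers")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols")
    classes = _as_class_set(classes)
    s_index = {s: i for i, s in enumerate(samples)}
    g_index = {g: j for j, g in enumerate(genes)}
    mat = np.zeros((len(samples), len(genes)), dtype=np.int8)
    skipped = 0
    for r in records:
        if r.mutation_class not in classes:
            continue
        i = s_index.get(r.sample)
        j = g_index.get(r.gene)
        if i is None:
            skipped += 1
            continue
        if j is None:
            continue
        mat[i, j] = 1
    if skipped:
        logger.info("ignored %d records for samples outside the cohort", skipped)
    return MutationMatrix(
        data=pd.DataFrame(mat, index=samples, columns=genes),
        class_filter=classes,
    )


def alteration_frequency(matrix: MutationMatrix) -> pd.Series:
    """Per-gene fraction of samples with >= 1 qualifying mutation."""
    return matrix.data.mean(axis=0)


@dataclass(frozen=True)
class GeneMutationProfile:
    """Per-gene mutation burden summary."""

    gene: str
    n_mutations: int
    n_mutated_samples: int
    coding_length: int
    in_family: bool

    @property
    def normalized_rate(self) -> float:
        """Mutation events per coding base."""
        return self.n_mutations / self.coding_length


def write_matrix(matrix: MutationMatrix, path) -> None:
    """Write the samples x genes indicator table as TSV."""
    matrix.data.to_csv(path, sep="\t", index_label="sample")


def write_profiles(profiles: Sequence["GeneMutationProfile"], path) -> None:
    """Write per-gene profiles (counts, length, rate, family flag) as TSV."""
    pd.DataFrame([{
        "gene": p.gene, "n_mutations": p.n_mutations,
        "n_mutated_samples": p.n_mutated_samples,
        "coding_length": p.coding_length,
        "normalized_rate": p.normalized_rate,
        "in_family": int(p.in_family),
    } for p in profiles]).to_csv(path, sep="\t", index=False)


def gene_profiles(records: Sequence[MutationRecord], gene_lengths: Mapping[str, int],
                  family_genes: Iterable[str],
                  classes=None) -> list[GeneMutationProfile]:
    """Aggregate per-gene counts into :class:`GeneMutationProfile` objects.

    Every gene in ``gene_lengths`` gets a profile (zero counts when unmutated).
    Records for genes without a length entry are excluded with a warning.
    ``classes`` optionally restricts which mutation classes are counted
    (default: all classes).
    """
    family = set(family_genes)
    class_set = _as_class_set(classes) if classes is not None else None
    n_mut: dict[str, int] = {g: 0 for g in gene_lengths}
    mutated_samples: dict[str, set] = {g: set() for g in gene_lengths}
    missing = set()
    for g, length in gene_lengths.items():
        if length <= 0:
            raise DataError(f"gene {g} has nonpositive coding length {length}")
    for r in records:
        if class_set is not None and r.mutation_class not in class_set:
            continue
        if r.gene not in n_mut:
            missing.add(r.gene)
            continue
        n_mut[r.gene] += 1
        mutated_samples[r.gene].add(r.sample)
    if missing:
        logger.warning("excluded %d gene(s) lacking a length entry: %s",
                       len(missing), sorted(missing)[:10])
    return [
        GeneMutationProfile(
            gene=g,
            n_mutations=n_mut[g],
            n_mutated_samples=len(mutated_samples[g]),
            coding_length=int(gene_lengths[g]),
            in_family=g in family,
        )
        for g in gene_lengths
    ]
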