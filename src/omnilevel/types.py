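"""Core domain containers shared across the pipeline.

Genomic coordinates are 1-based inclusive throughout (the native convention of
segmented copy-number files); BED input is converted at the I/O boundary.
Matrices are features x samples with missing values represented as NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("GE", "CN", "ME", "MR", "GM")

MATRIX_KINDS = ("expression", "copy_number", "beta", "mirna")


@dataclass(frozen=True)
class GeneModel:
    """One gene's genomic footprint (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment; seg_value is log2(copy/2)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )
        if not np.isfinite(self.seg_value):
            raise ValueError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}: "
                "seg_value not finite"
            )

    @property
    def linear_copy(self) -> float:
        """Linear copy number, 2 * 2**seg_value."""
        return 2.0 * 2.0 ** self.seg_value


@dataclass(frozen=True)
class MutationCall:
    """One somatic mutation call (gene, sample, variant class)."""

    gene_id: str
    sample_id: str
    variant_classification: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("MutationCall gene_id must be non-empty")
        if not self.sample_id:
            raise ValueError("MutationCall sample_id must be non-empty")


class OmicsMatrix:
    """Features x samples value matrix of a declared kind.

    ``beta`` matrices must lie in [0, 1]; ``expression``/``mirna``/
    ``copy_number`` must be non-negative.  NaN marks missing values and is
    excluded pairwise/groupwise from downstream statistics.
    """

    def __init__(self, data: pd.DataFrame, kind: str):
        if kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {kind!r}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        data = data.astype(float)
        vals = data.to_numpy()
        finite = vals[~np.isnan(vals)]
        if kind == "beta":
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError(
                    f"beta values outside [0, 1]: range "
                    f"[{finite.min():g}, {finite.max():g}]"
                )
        else:
            if finite.size and finite.min() < 0.0:
                raise ValueError(f"{kind} values must be >= 0 (min {finite.min():g})")
        self.data = data
        self.kind = kind

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OmicsMatrix)
            and self.kind == other.kind
            and self.data.shape == other.data.shape
            and list(self.data.index) == list(other.data.index)
            and list(self.data.columns) == list(other.data.columns)
            and np.allclose(
                self.data.to_numpy(), other.data.to_numpy(), equal_nan=True
            )
        )

    def __repr__(self) -> str:
        return f"OmicsMatrix(kind={self.kind!r}, shape={self.shape})"


@dataclass
class SampleDesign:
    """Tumor/normal group labels with optional tumor<->normal pairing."""

    tumor: list[str]
    normal: list[str]
    pairs: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.tumor)) != len(self.tumor):
            raise ValueError("duplicate tumor sample IDs")
        if len(set(self.normal)) != len(self.normal):
            raise ValueError("duplicate normal sample IDs")
        if set(self.tumor) & set(self.normal):
            raise ValueError("sample appears in both tumor and normal groups")
        if self.pairs is not None:
            tset, nset = set(self.tumor), set(self.normal)
            for t, n in self.pairs:
                if t not in tset:
                    raise ValueError(f"paired tumor sample {t!r} not in tumor group")
                if n not in nset:
                    raise ValueError(f"paired normal sample {n!r} not in normal group")

    @property
    def n_tumor(self) -> int:
        return len(self.tumor)

    @property
    def n_normal(self) -> int:
        return len(self.normal)


@dataclass
class ThresholdConfig:
    """Calling thresholds for the five screens.

    Defaults are the study's operating point: two-fold expression, 1.2-fold
    copy number, 5% beta-value depression, two-fold miRNA depression (each at
    BH FDR <= 0.05) and raw Fisher p < 0.05 for mutations.
    """

    ge_fold: float = 2.0
    ge_fdr: float = 0.05
    cn_fold: float = 1.2
    cn_fdr: float = 0.05
    me_delta_beta: float = 0.05
    me_fdr: float = 0.05
    mr_fold: float = 2.0
    mr_fdr: float = 0.05
    gm_p: float = 0.05
    min_pairs: int = 3
    min_group: int = 2
    t_variant: str = "welch"  # welch | student
    segment_weighting: str = "length"  # length | unweighted
    gm_use_fdr: bool = False

    def __post_init__(self) -> None:
        for name in ("ge_fold", "cn_fold", "mr_fold"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1 (got {getattr(self, name)})")
        for name in ("ge_fdr", "cn_fdr", "me_fdr", "mr_fdr", "gm_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1) (got {v})")
        if not (0.0 < self.me_delta_beta < 1.0):
            raise ValueError("me_delta_beta must be in (0, 1)")
        if self.t_variant not in ("welch", "student"):
            raise ValueError(f"t_variant must be welch|student (got {self.t_variant})")
        if self.segment_weighting not in ("length", "unweighted"):
            raise ValueError("segment_weighting must be length|unweighted")


@dataclass
class ScreenResult:
    """Per-feature outcome of one modality screen.

    ``table`` is indexed by feature ID with at least columns
    ``effect`` (fold change, delta-beta or odds ratio), ``p``, ``q``,
    ``tested`` and ``called``.  ``q`` is NaN for the mutation screen, which
    uses raw p-values.
    """

    modality: str
    table: pd.DataFrame
    n_case: int
    n_comparison: int

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        for col in ("effect", "p", "q", "tested", "called"):
            if col not in self.table.columns:
                raise ValueError(f"ScreenResult table missing column {col!r}")

    @property
    def called_set(self) -> set[str]:
        return set(self.table.index[self.table["called"].astype(bool)])

    @property
    def tested_set(self) -> set[str]:
        return set(self.table.index[self.table["tested"].astype(bool)])

    @property
    def n_called(self) -> int:
        return int(self.table["called"].astype(bool).sum())


@dataclass
class SyntheticTruth:
    """Planted features per modality with planted effect sizes.

    ``planted`` maps modality -> {feature_id: effect}; for MR the features are
    the planted target genes and for the miRNA layer itself
    ``planted_mirnas`` holds the planted fold depressions.
    ``expected_level`` gives the nominal evidence level of each planted GE
    gene implied by the planting design.
    """

    planted: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_mirnas: dict[str, float] = field(default_factory=dict)
    expected_level: dict[str, int] = field(default_factory=dict)

    def planted_set(self, modality: str) -> set[str]:
        return set(self.planted.get(modality, {}))
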