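"""The five per-modality hyperactivation screens.

Each screen compares tumor against normal samples in one data type and calls a
feature "hyperactivated" only when an effect-size floor and a significance
threshold are met jointly:

* GE — paired expression: fold = mean(tumor)/mean(normal) over usable pairs,
  Wilcoxon signed-rank on paired differences, BH FDR.
* CN — gene-level linear copy number derived from segment files, same paired
  scheme with a lower fold floor (copy-number differences are compressed).
* ME — hypomethylation: delta-beta = mean(normal) - mean(tumor) on two
  platforms, rank-sum per platform; a gene must pass on both.
* MR — loss of miRNA repression: miRNAs downregulated in tumors (Welch t on
  log2(x+1), BH FDR, fold floor on raw means) vote their predicted target
  genes into the MR set.
* GM — mutation enrichment: per-gene 2x2 Fisher exact test of the case cohort
  against the background cohort, raw p threshold with odds ratio > 1.

Fold changes are ratios of group means (not means of per-pair ratios), which
is stable when individual normal values approach zero.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats_core import (
    ContingencyTable2x2,
    bh_fdr,
    fisher_exact,
    two_sample_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .types import (
    GeneModel,
    MutationCall,
    OmicsMatrix,
    SampleDesign,
    ScreenResult,
    SegmentRecord,
    ThresholdConfig,
)

logger = logging.getLogger("omnilevel")

NEUTRAL_COPY = 2.0

#: Variant classes never counted as qualifying mutations under the default filter.
SILENT_CLASSES = frozenset({"Silent"})


def _result_frame(index: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "effect": np.nan,
            "p": np.nan,
            "q": np.nan,
            "tested": False,
            "called": False,
        },
        index=pd.Index(index, name="feature_id"),
    )
    return df


def _paired_screen(
    matrix: OmicsMatrix,
    design: SampleDesign,
    fold_threshold: float,
    fdr_threshold: float,
    modality: str,
    min_pairs: int,
) -> ScreenResult:
    if not design.pairs:
        raise ValueError(f"{modality} screen requires a paired design")
    have = set(matrix.samples)
    pairs = [(t, n) for t, n in design.pairs if t in have and n in have]
    if not pairs:
        raise ValueError(f"{modality} screen: no tumor/normal pairs present in matrix")
    tumor = matrix.data[[t for t, _ in pairs]].to_numpy()
    normal = matrix.data[[n for _, n in pairs]].to_numpy()
    df = _result_frame(matrix.features)
    effects = np.full(len(df), np.nan)
    pvals = np.full(len(df), np.nan)
    tested = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        t, n = tumor[i], normal[i]
        ok = ~np.isnan(t) & ~np.isnan(n)
        t, n = t[ok], n[ok]
        if t.size < min_pairs:
            continue
        mean_n = float(n.mean())
        if mean_n == 0.0:
            continue
        diffs = t - n
        if np.all(diffs == 0.0):
            continue  # no paired signal at all: untested, not called
        effects[i] = float(t.mean()) / mean_n
        pvals[i] = wilcoxon_signed_rank(diffs).p_value
        tested[i] = True
    qvals = bh_fdr(np.where(tested, pvals, np.nan))
    df["effect"] = effects
    df["p"] = pvals
    df["q"] = qvals
    df["tested"] = tested
    df["called"] = tested & (effects >= fold_threshold) & (qvals <= fdr_threshold)
    df["n_pairs"] = len(pairs)
    return ScreenResult(
        modality=modality, table=df, n_case=len(pairs), n_comparison=len(pairs)
    )


def screen_expression(
    expr: OmicsMatrix, design: SampleDesign, cfg: ThresholdConfig
) -> ScreenResult:
    """Paired tumor-vs-normal upregulation screen on an expression matrix."""
    return _paired_screen(expr, design, cfg.ge_fold, cfg.ge_fdr, "GE", cfg.min_pairs)


@dataclass
class GeneCopyResult:
    """Gene-level linear copy numbers plus the neutral-imputation mask."""

    copies: OmicsMatrix
    imputed: pd.DataFrame  # same shape, True where no segment covered the gene


def map_segments_to_genes(
    segments: Sequence[SegmentRecord],
    genes: Sequence[GeneModel],
    samples: Sequence[str] | None = None,
    weighting: str = "length",
) -> GeneCopyResult:
    """Annotate genes with copy number from overlapping segments.

    Each overlapping segment contributes its linear copy number
    ``2 * 2**seg_value``; the gene value is the overlap-length-weighted mean
    (``weighting="length"``, the default) or the unweighted mean of
    overlapping segments.  Genes with no covering segment in a sample are
    imputed copy-neutral (2.0) and flagged, because "nocnv" segment files
    omit copy-neutral regions.
    """
    if weighting not in ("length", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not genes:
        raise ValueError("gene model is empty")
    if samples is None:
        samples = sorted({s.sample_id for s in segments})
    samples = list(samples)
    trees: dict[tuple[str, str], IntervalTree] = {}
    seg_chroms: set[str] = set()
    for seg in segments:
        seg_chroms.add(seg.chrom)
        # interval tree is half-open; store [start, end+1)
        trees.setdefault((seg.sample_id, seg.chrom), IntervalTree()).addi(
            seg.start, seg.end + 1, seg.linear_copy
        )
    gene_chroms = {g.chrom for g in genes}
    if segments and not (gene_chroms & seg_chroms):
        logger.warning(
            "no chromosome shared between gene model (%s) and segments (%s); "
            "all copy numbers imputed neutral",
            sorted(gene_chroms)[:5],
            sorted(seg_chroms)[:5],
        )
    values = np.full((len(genes), len(samples)), NEUTRAL_COPY)
    imputed = np.ones((len(genes), len(samples)), dtype=bool)
    for j, sample in enumerate(samples):
        for i, gene in enumerate(genes):
            tree = trees.get((sample, gene.chrom))
            if tree is None:
                continue
            hits = tree.overlap(gene.start, gene.end + 1)
            if not hits:
                continue
            copies = []
            weights = []
            for iv in hits:
                olap = min(iv.end - 1, gene.end) - max(iv.begin, gene.start) + 1
                copies.append(iv.data)
                weights.append(olap)
            if weighting == "length":
                values[i, j] = float(np.average(copies, weights=weights))
            else:
                values[i, j] = float(np.mean(copies))
            imputed[i, j] = False
    gene_ids = [g.gene_id for g in genes]
    copies = OmicsMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples), "copy_number"
    )
    mask = pd.DataFrame(imputed, index=gene_ids, columns=samples)
    return GeneCopyResult(copies=copies, imputed=mask)


def screen_copy_number(
    copies: OmicsMatrix | GeneCopyResult, design: SampleDesign, cfg: ThresholdConfig
) -> ScreenResult:
    """Paired copy-number-gain screen on gene-level linear copy numbers.

    Genes whose paired differences are identically zero (e.g. all samples
    imputed neutral) are reported untested.
    """
    matrix = copies.copies if isinstance(copies, GeneCopyResult) else copies
    return _paired_screen(matrix, design, cfg.cn_fold, cfg.cn_fdr, "CN", cfg.min_pairs)


def collapse_probes_to_genes(
    beta: OmicsMatrix, probe_map: Mapping[str, str]
) -> OmicsMatrix:
    """Collapse a probe-level beta matrix to gene level.

    Gene beta per sample is the unweighted mean over mapped probes with
    non-missing values; unmapped probes are dropped with a logged count.
    """
    mapped = [p for p in beta.features if p in probe_map]
    dropped = len(beta.features) - len(mapped)
    if dropped:
        logger.info("collapse_probes_to_genes: dropped %d unmapped probes", dropped)
    if not mapped:
        return OmicsMatrix(pd.DataFrame(columns=beta.samples, dtype=float), "beta")
    sub = beta.data.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="feature_id")
    collapsed = sub.groupby(genes).mean()  # skips NaN per cell
    return OmicsMatrix(collapsed.sort_index(), "beta")


def _unpaired_delta_beta(
    beta: OmicsMatrix, design: SampleDesign, min_group: int
) -> pd.DataFrame:
    tumor_cols = [s for s in design.tumor if s in beta.samples]
    normal_cols = [s for s in design.normal if s in beta.samples]
    if not tumor_cols or not normal_cols:
        raise ValueError("methylation platform lacks tumor or normal samples")
    T = beta.data[tumor_cols].to_numpy()
    N = beta.data[normal_cols].to_numpy()
    out = pd.DataFrame(
        {"delta_beta": np.nan, "p": np.nan, "tested": False},
        index=pd.Index(beta.features, name="feature_id"),
    )
    deltas = np.full(len(out), np.nan)
    pvals = np.full(len(out), np.nan)
    tested = np.zeros(len(out), dtype=bool)
    for i in range(len(out)):
        t = T[i][~np.isnan(T[i])]
        n = N[i][~np.isnan(N[i])]
        if t.size < min_group or n.size < min_group:
            continue
        deltas[i] = float(n.mean()) - float(t.mean())
        pvals[i] = wilcoxon_rank_sum(t, n).p_value
        tested[i] = True
    out["delta_beta"] = deltas
    out["p"] = pvals
    out["q"] = bh_fdr(np.where(tested, pvals, np.nan))
    out["tested"] = tested
    return out


def screen_methylation(
    beta_a: OmicsMatrix,
    beta_b: OmicsMatrix,
    design_a: SampleDesign,
    design_b: SampleDesign,
    cfg: ThresholdConfig,
) -> ScreenResult:
    """Two-platform hypomethylation screen on gene-level beta matrices.

    A gene is called only if on BOTH platforms the tumor beta mean sits at
    least ``me_delta_beta`` below the normal mean (rank-sum q <= me_fdr); the
    result records per-platform statistics and the intersection call.
    """
    a = _unpaired_delta_beta(beta_a, design_a, cfg.min_group)
    b = _unpaired_delta_beta(beta_b, design_b, cfg.min_group)
    all_genes = sorted(set(a.index) | set(b.index))
    df = _result_frame(all_genes)
    for tag, part in (("a", a), ("b", b)):
        for col in ("delta_beta", "p", "q"):
            df[f"{col}_{tag}"] = part[col].reindex(df.index)
        df[f"tested_{tag}"] = part["tested"].reindex(df.index).fillna(False).astype(bool)
    df["tested"] = df["tested_a"] & df["tested_b"]
    pass_a = (
        df["tested_a"]
        & (df["delta_beta_a"] >= cfg.me_delta_beta)
        & (df["q_a"] <= cfg.me_fdr)
    )
    pass_b = (
        df["tested_b"]
        & (df["delta_beta_b"] >= cfg.me_delta_beta)
        & (df["q_b"] <= cfg.me_fdr)
    )
    df["called"] = (pass_a & pass_b).to_numpy()
    # summary columns: the weaker platform determines the reported statistics
    df["effect"] = df[["delta_beta_a", "delta_beta_b"]].min(axis=1)
    df["p"] = df[["p_a", "p_b"]].max(axis=1)
    df["q"] = df[["q_a", "q_b"]].max(axis=1)
    return ScreenResult(
        modality="ME",
        table=df,
        n_case=design_a.n_tumor + design_b.n_tumor,
        n_comparison=design_a.n_normal + design_b.n_normal,
    )


def screen_mirna(
    mirna: OmicsMatrix, design: SampleDesign, cfg: ThresholdConfig
) -> ScreenResult:
    """Unpaired miRNA downregulation screen.

    fold = mean(normal)/mean(tumor) on the raw scale; the t-test runs on
    log2(x+1)-transformed values.
    """
    tumor_cols = [s for s in design.tumor if s in mirna.samples]
    normal_cols = [s for s in design.normal if s in mirna.samples]
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("miRNA screen requires >= 2 samples per group")
    T = mirna.data[tumor_cols].to_numpy()
    N = mirna.data[normal_cols].to_numpy()
    df = _result_frame(mirna.features)
    effects = np.full(len(df), np.nan)
    pvals = np.full(len(df), np.nan)
    tested = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        t = T[i][~np.isnan(T[i])]
        n = N[i][~np.isnan(N[i])]
        if t.size < max(2, cfg.min_group) or n.size < max(2, cfg.min_group):
            continue
        mean_t, mean_n = float(t.mean()), float(n.mean())
        if mean_t == 0.0 and mean_n == 0.0:
            continue
        effects[i] = math.inf if mean_t == 0.0 else mean_n / mean_t
        out = two_sample_t(np.log2(t + 1.0), np.log2(n + 1.0), variant=cfg.t_variant)
        pvals[i] = out.p_value
        tested[i] = True
    qvals = bh_fdr(np.where(tested, pvals, np.nan))
    df["effect"] = effects
    df["p"] = pvals
    df["q"] = qvals
    df["tested"] = tested
    df["called"] = tested & (effects >= cfg.mr_fold) & (qvals <= cfg.mr_fdr)
    return ScreenResult(
        modality="MR", table=df, n_case=len(tumor_cols), n_comparison=len(normal_cols)
    )


def map_mirna_targets(
    down_mirnas: Iterable[str], targets: Mapping[str, Iterable[str]]
) -> set[str]:
    """Union of target genes over downregulated miRNAs (the MR gene set)."""
    genes: set[str] = set()
    missing = []
    for mirna in sorted(set(down_mirnas)):
        if mirna not in targets:
            missing.append(mirna)
            continue
        genes.update(targets[mirna])
    if missing:
        logger.warning(
            "map_mirna_targets: %d called miRNAs absent from the target map: %s",
            len(missing),
            missing[:5],
        )
    return genes


@dataclass
class MutationMatrix:
    """Binary genes x samples matrix; entry 1 iff >= 1 qualifying mutation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def build_mutation_matrix(
    calls: Sequence[MutationCall],
    samples: Sequence[str],
    classification_filter: str | Iterable[str] = "nonsilent",
) -> MutationMatrix:
    """Build the binary mutation matrix over the supplied sample list.

    ``classification_filter`` is ``"all"`` (keep every call), ``"nonsilent"``
    (drop Silent calls; the default) or an explicit set of retained
    Variant_Classification strings.  Duplicate calls collapse to 1; calls for
    samples outside the list are dropped with a logged count; rows are
    restricted to genes with at least one retained call.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample IDs in mutation matrix")
    if isinstance(classification_filter, str):
        if classification_filter == "all":
            keep = None
        elif classification_filter == "nonsilent":
            keep = None  # handled via exclusion below
        else:
            raise ValueError(f"unknown classification filter {classification_filter!r}")
        exclude = SILENT_CLASSES if classification_filter == "nonsilent" else frozenset()
    else:
        keep = frozenset(classification_filter)
        exclude = frozenset()
    sample_set = set(samples)
    hits: dict[str, set[str]] = {}
    dropped_samples = 0
    for call in calls:
        if keep is not None and call.variant_classification not in keep:
            continue
        if call.variant_classification in exclude:
            continue
        if call.sample_id not in sample_set:
            dropped_samples += 1
            continue
        hits.setdefault(call.gene_id, set()).add(call.sample_id)
    if dropped_samples:
        logger.info(
            "build_mutation_matrix: dropped %d calls for samples outside the cohort",
            dropped_samples,
        )
    genes = sorted(hits)
    data = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for gene, mutated in hits.items():
        data.loc[gene, sorted(mutated)] = 1
    return MutationMatrix(data=data)


def screen_mutations(
    case_matrix: MutationMatrix,
    background_matrix: MutationMatrix,
    cfg: ThresholdConfig,
) -> ScreenResult:
    """Per-gene mutation-enrichment screen, case cohort vs background cohort.

    The 2x2 table is (case mutated, case wild-type; background mutated,
    background wild-type); the background defaults to the full cohort
    including the cases.  Calls use the raw Fisher p (< gm_p) together with
    odds ratio > 1; no FDR correction by default (``gm_use_fdr`` adds BH q
    without changing the call rule).
    """
    n_case = case_matrix.n_samples
    n_bg = background_matrix.n_samples
    if n_case == 0:
        raise ValueError("mutation screen requires at least one case sample")
    if n_bg == 0:
        raise ValueError("mutation screen requires a background cohort")
    genes = sorted(set(case_matrix.data.index) | set(background_matrix.data.index))
    df = _result_frame(genes)
    effects = np.full(len(df), np.nan)
    pvals = np.full(len(df), np.nan)
    case_counts = np.zeros(len(df), dtype=int)
    bg_counts = np.zeros(len(df), dtype=int)
    for i, gene in enumerate(genes):
        a = (
            int(case_matrix.data.loc[gene].sum())
            if gene in case_matrix.data.index
            else 0
        )
        c = (
            int(background_matrix.data.loc[gene].sum())
            if gene in background_matrix.data.index
            else 0
        )
        table = ContingencyTable2x2(a, n_case - a, c, n_bg - c)
        odds, outcome = fisher_exact(table)
        effects[i] = odds
        pvals[i] = outcome.p_value
        case_counts[i] = a
        bg_counts[i] = c
    df["effect"] = effects
    df["p"] = pvals
    if cfg.gm_use_fdr:
        df["q"] = bh_fdr(pvals)
    df["tested"] = True
    df["called"] = (pvals < cfg.gm_p) & (effects > 1.0)
    df["n_mutated_case"] = case_counts
    df["n_mutated_background"] = bg_counts
    df["case_rate"] = case_counts / n_case
    df["background_rate"] = bg_counts / n_bg
    return ScreenResult(modality="GM", table=df, n_case=n_case, n_comparison=n_bg)
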