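"""Seeded multi-omics study generator with planted per-modality effects.

The generator emulates the shape of a TCGA-style triple-negative breast
cancer cohort: paired tumor/normal expression (55 pairs) and copy-number
segment sets (53 pairs), probe-level methylation beta matrices on two
platforms (32 vs 27 and 23 vs 47 samples), unpaired miRNA expression
(53 vs 103), and somatic mutation calls for 54 case samples inside a
992-sample background cohort.  Planted effects per modality (expression fold,
copy gain, beta depression, miRNA depression, elevated case mutation rate)
follow a deterministic overlap design so that planted genes span evidence
Levels 1-5, and a ground-truth table records every planted feature with its
expected level.

All randomness flows from a single seed through one child stream per
modality, so each modality is independently reproducible.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .types import (
    GeneModel,
    MutationCall,
    OmicsMatrix,
    SampleDesign,
    SegmentRecord,
    SyntheticTruth,
)

NONSILENT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del")

_STREAMS = ("expression", "cnv", "methylation", "mirna", "mutation", "targets")


@dataclass
class SimulationConfig:
    """Study shape, planted effects and noise model.

    Cohort-shape defaults mirror the reference TCGA-like cohort (55
    expression pairs, 53 copy-number pairs, 32/27 and 23/47 methylation
    samples, 53/103 miRNA samples, 54 cases in a 992-sample mutation
    cohort); all are overridable for fast tests.
    """

    seed: int
    n_genes: int = 2000
    n_mirnas: int = 200
    n_planted: int = 100  # per modality
    # cohort shapes
    n_pairs_expression: int = 55
    n_pairs_cnv: int = 53
    me_a_tumor: int = 32
    me_a_normal: int = 27
    me_b_tumor: int = 23
    me_b_normal: int = 47
    mirna_tumor: int = 53
    mirna_normal: int = 103
    n_case_maf: int = 54
    n_background_maf: int = 992
    # planted effect sizes
    ge_fold: float = 4.0
    cn_copy: float = 3.0  # planted linear tumor copy (fold 1.5 over neutral 2)
    me_delta: float = 0.2  # beta depression in tumors
    mirna_fold: float = 4.0  # normal/tumor mean ratio for planted miRNAs
    mut_rate_case: float = 0.4
    mut_rate_background: float = 0.05
    # nuisance / noise model
    expr_baseline_mean: float = 8.0  # log2 units
    expr_baseline_sd: float = 2.0
    expr_noise_sd: float = 0.5  # log2 within-group noise
    seg_noise_sd: float = 0.05  # log2 noise per emitted segment
    beta_concentration: float = 60.0
    probes_min: int = 2
    probes_max: int = 5
    baseline_mut_rate: float = 0.002  # long-tail somatic rate per gene/sample
    silent_rate: float = 0.002
    targets_per_mirna: int = 5
    # toy genome geometry
    gene_length: int = 10_000
    gene_spacing: int = 10_000
    genes_per_chrom: int = 200

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("n_genes and n_mirnas must be positive")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        for name in ("ge_fold", "mirna_fold"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1")
        if self.cn_copy <= 2.0:
            raise ValueError("cn_copy must exceed the neutral copy number 2")
        if not (0.0 < self.me_delta < 1.0):
            raise ValueError("me_delta must be in (0, 1)")
        for name in ("mut_rate_case", "mut_rate_background", "baseline_mut_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.n_case_maf > self.n_background_maf:
            raise ValueError("case cohort cannot exceed the background cohort")
        if self.probes_min < 1 or self.probes_max < self.probes_min:
            raise ValueError("invalid probe count range")
        if self.targets_per_mirna < 1:
            raise ValueError("targets_per_mirna must be >= 1")
        shapes = (
            self.n_pairs_expression,
            self.n_pairs_cnv,
            self.me_a_tumor,
            self.me_a_normal,
            self.me_b_tumor,
            self.me_b_normal,
            self.mirna_tumor,
            self.mirna_normal,
            self.n_case_maf,
        )
        if min(shapes) < 2:
            raise ValueError("every cohort group needs >= 2 samples")
        plan = plan_planted(self.n_genes, self.n_planted)  # validates capacity
        n_planted_mirnas = -(-len(plan["MR"]) // self.targets_per_mirna)
        if n_planted_mirnas > self.n_mirnas:
            raise ValueError("too few miRNAs to carry the planted MR targets")


def plan_planted(n_genes: int, n_planted: int) -> dict[str, list[int]]:
    """Deterministic planted-gene index blocks with structured overlap.

    GE gets the first ``n_planted`` genes.  A core block (40% of the planted
    count) is shared by GE, CN and ME; MR overlaps GE across a shifted core
    window; GM shares a small core slice.  Each modality tops up with fresh
    genes to exactly ``n_planted``, so planted genes span evidence levels
    from 1 (GE only) to 5 (all modalities).
    """
    if n_planted == 0:
        return {m: [] for m in ("GE", "CN", "ME", "MR", "GM")}
    n = n_planted
    core = max(1, (2 * n) // 5)
    mr_start = core // 2
    mr_core = min(core, n - mr_start)
    gm_core = core // 4
    cursor = n

    def fresh(size: int) -> list[int]:
        nonlocal cursor
        block = list(range(cursor, cursor + size))
        cursor += size
        return block

    plan = {
        "GE": list(range(0, n)),
        "CN": list(range(0, core)) + fresh(n - core),
        "ME": list(range(0, core)) + fresh(n - core),
        "MR": list(range(mr_start, mr_start + mr_core)) + fresh(n - mr_core),
        "GM": list(range(0, gm_core)) + fresh(n - gm_core),
    }
    if cursor > n_genes:
        raise ValueError(
            f"n_genes={n_genes} too small for n_planted={n_planted} "
            f"(needs >= {cursor})"
        )
    return plan


@dataclass
class Study:
    """A complete in-memory multi-omics study plus its ground truth."""

    config: SimulationConfig
    gene_ids: list[str]
    gene_model: list[GeneModel]
    expression: OmicsMatrix
    expression_design: SampleDesign
    segments: list[SegmentRecord]
    cnv_design: SampleDesign
    beta_a: OmicsMatrix
    probe_map_a: dict[str, str]
    design_a: SampleDesign
    beta_b: OmicsMatrix
    probe_map_b: dict[str, str]
    design_b: SampleDesign
    mirna: OmicsMatrix
    mirna_design: SampleDesign
    target_map: dict[str, set[str]]
    maf_calls: list[MutationCall]
    case_samples: list[str]
    background_samples: list[str]
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"miR-{i:0{width}d}" for i in range(n)]


def _build_gene_model(cfg: SimulationConfig, gene_ids: list[str]) -> list[GeneModel]:
    step = cfg.gene_length + cfg.gene_spacing
    model = []
    for i, gid in enumerate(gene_ids):
        chrom = str(i // cfg.genes_per_chrom + 1)
        j = i % cfg.genes_per_chrom
        start = cfg.gene_spacing + j * step + 1
        model.append(GeneModel(gid, chrom, start, start + cfg.gene_length - 1))
    return model


def _lognormal_matrix(
    rng: np.random.Generator,
    baseline: np.ndarray,
    tumor_shift: np.ndarray,
    n_tumor: int,
    n_normal: int,
    noise_sd: float,
    tumor_prefix: str,
    normal_prefix: str,
    feature_ids: list[str],
    kind: str,
) -> tuple[OmicsMatrix, list[str], list[str]]:
    g = baseline.size
    tumor = 2.0 ** (
        baseline[:, None] + tumor_shift[:, None] + rng.normal(0, noise_sd, (g, n_tumor))
    )
    normal = 2.0 ** (baseline[:, None] + rng.normal(0, noise_sd, (g, n_normal)))
    t_ids = [f"{tumor_prefix}{i:03d}" for i in range(n_tumor)]
    n_ids = [f"{normal_prefix}{i:03d}" for i in range(n_normal)]
    data = pd.DataFrame(
        np.concatenate([tumor, normal], axis=1),
        index=feature_ids,
        columns=t_ids + n_ids,
    )
    return OmicsMatrix(data, kind), t_ids, n_ids


def _generate_segments(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_model: list[GeneModel],
    planted_idx: list[int],
) -> tuple[list[SegmentRecord], SampleDesign]:
    step = cfg.gene_length + cfg.gene_spacing
    chrom_extent = cfg.gene_spacing + cfg.genes_per_chrom * step
    chroms = sorted({g.chrom for g in gene_model}, key=int)
    planted = set(planted_idx)
    # template of (chrom, start, end, amplified) intervals shared by tumors
    amplified: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    run: list[int] = []
    for i in sorted(planted) + [-1]:
        if run and (i != run[-1] + 1 or i % cfg.genes_per_chrom == 0):
            first, last = gene_model[run[0]], gene_model[run[-1]]
            amplified[first.chrom].append((first.start, last.end))
            run = []
        if i >= 0:
            run.append(i)
    template: list[tuple[str, int, int, bool]] = []
    for chrom in chroms:
        cur = 1
        for s, e in sorted(amplified[chrom]):
            if s > cur:
                template.append((chrom, cur, s - 1, False))
            template.append((chrom, s, e, True))
            cur = e + 1
        if cur <= chrom_extent:
            template.append((chrom, cur, chrom_extent, False))

    n = cfg.n_pairs_cnv
    t_ids = [f"CN_T{i:03d}" for i in range(n)]
    n_ids = [f"CN_N{i:03d}" for i in range(n)]
    amp_value = math.log2(cfg.cn_copy / 2.0)
    records: list[SegmentRecord] = []
    for sid in t_ids:
        for chrom, s, e, is_amp in template:
            value = (amp_value if is_amp else 0.0) + float(
                rng.normal(0, cfg.seg_noise_sd)
            )
            records.append(SegmentRecord(sid, chrom, s, e, value))
    for sid in n_ids:
        for chrom in chroms:
            value = float(rng.normal(0, cfg.seg_noise_sd))
            records.append(SegmentRecord(sid, chrom, 1, chrom_extent, value))
    design = SampleDesign(tumor=t_ids, normal=n_ids, pairs=list(zip(t_ids, n_ids)))
    return records, design


def _generate_beta_platform(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_ids: list[str],
    baseline: np.ndarray,
    planted_idx: list[int],
    platform: str,
    n_tumor: int,
    n_normal: int,
) -> tuple[OmicsMatrix, dict[str, str], SampleDesign]:
    planted = set(planted_idx)
    tumor_means = baseline.copy()
    tumor_means[list(planted)] -= cfg.me_delta
    n_probes = rng.integers(cfg.probes_min, cfg.probes_max + 1, size=len(gene_ids))
    probe_gene_idx = np.repeat(np.arange(len(gene_ids)), n_probes)
    probe_ids = []
    counter: dict[str, int] = {}
    for gi in probe_gene_idx:
        gid = gene_ids[gi]
        k = counter.get(gid, 0)
        counter[gid] = k + 1
        probe_ids.append(f"{platform}_{gid}_p{k}")
    kappa = cfg.beta_concentration
    tm = tumor_means[probe_gene_idx]
    nm = baseline[probe_gene_idx]
    tumor_vals = rng.beta(
        tm[:, None] * kappa, (1 - tm[:, None]) * kappa, (len(probe_ids), n_tumor)
    )
    normal_vals = rng.beta(
        nm[:, None] * kappa, (1 - nm[:, None]) * kappa, (len(probe_ids), n_normal)
    )
    t_ids = [f"{platform}_T{i:03d}" for i in range(n_tumor)]
    n_ids = [f"{platform}_N{i:03d}" for i in range(n_normal)]
    data = pd.DataFrame(
        np.concatenate([tumor_vals, normal_vals], axis=1),
        index=probe_ids,
        columns=t_ids + n_ids,
    )
    probe_map = {pid: gene_ids[gi] for pid, gi in zip(probe_ids, probe_gene_idx)}
    design = SampleDesign(tumor=t_ids, normal=n_ids)
    return OmicsMatrix(data, "beta"), probe_map, design


def _generate_mutations(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_ids: list[str],
    planted_idx: list[int],
) -> tuple[list[MutationCall], list[str], list[str]]:
    n_case = cfg.n_case_maf
    n_bg = cfg.n_background_maf
    case_ids = [f"GM_T{i:03d}" for i in range(n_case)]
    extra_ids = [f"GM_B{i:03d}" for i in range(n_bg - n_case)]
    all_ids = case_ids + extra_ids  # background cohort includes the cases
    planted = set(planted_idx)
    rates = np.full((len(gene_ids), n_bg), cfg.baseline_mut_rate)
    for i in planted:
        rates[i, :n_case] = cfg.mut_rate_case
        rates[i, n_case:] = cfg.mut_rate_background
    hits = rng.random((len(gene_ids), n_bg)) < rates
    calls: list[MutationCall] = []
    gi, sj = np.nonzero(hits)
    classes = rng.integers(0, len(NONSILENT_CLASSES), size=gi.size)
    for g, s, c in zip(gi, sj, classes):
        calls.append(MutationCall(gene_ids[g], all_ids[s], NONSILENT_CLASSES[c]))
    silent = rng.random((len(gene_ids), n_bg)) < cfg.silent_rate
    for g, s in zip(*np.nonzero(silent)):
        calls.append(MutationCall(gene_ids[g], all_ids[s], "Silent"))
    return calls, case_ids, all_ids


def generate_study(cfg: SimulationConfig) -> Study:
    """Generate a complete seeded study with planted effects and ground truth."""
    plan = plan_planted(cfg.n_genes, cfg.n_planted)
    gene_ids = _gene_ids(cfg.n_genes)
    gene_model = _build_gene_model(cfg, gene_ids)
    ss = np.random.SeedSequence(cfg.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, ss.spawn(len(_STREAMS)))
    }

    # expression (paired)
    rng = rngs["expression"]
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_genes)
    shift = np.zeros(cfg.n_genes)
    shift[plan["GE"]] = math.log2(cfg.ge_fold)
    expr, t_ids, n_ids = _lognormal_matrix(
        rng,
        baseline,
        shift,
        cfg.n_pairs_expression,
        cfg.n_pairs_expression,
        cfg.expr_noise_sd,
        "GE_T",
        "GE_N",
        gene_ids,
        "expression",
    )
    expr_design = SampleDesign(
        tumor=t_ids, normal=n_ids, pairs=list(zip(t_ids, n_ids))
    )

    # copy number (paired segment sets)
    segments, cnv_design = _generate_segments(
        cfg, rngs["cnv"], gene_model, plan["CN"]
    )

    # methylation (two platforms, unpaired)
    rng = rngs["methylation"]
    beta_baseline = rng.uniform(0.3, 0.7, cfg.n_genes)
    beta_a, probe_map_a, design_a = _generate_beta_platform(
        cfg, rng, gene_ids, beta_baseline, plan["ME"], "HM27", cfg.me_a_tumor,
        cfg.me_a_normal,
    )
    beta_b, probe_map_b, design_b = _generate_beta_platform(
        cfg, rng, gene_ids, beta_baseline, plan["ME"], "HM450", cfg.me_b_tumor,
        cfg.me_b_normal,
    )

    # miRNA (unpaired, planted miRNAs downregulated in tumors)
    rng = rngs["mirna"]
    mirna_ids = _mirna_ids(cfg.n_mirnas)
    mr_genes = [gene_ids[i] for i in plan["MR"]]
    n_planted_mirnas = -(-len(mr_genes) // cfg.targets_per_mirna) if mr_genes else 0
    mirna_baseline = rng.normal(
        cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_mirnas
    )
    mirna_shift = np.zeros(cfg.n_mirnas)
    mirna_shift[:n_planted_mirnas] = -math.log2(cfg.mirna_fold)
    mirna, mr_t, mr_n = _lognormal_matrix(
        rng,
        mirna_baseline,
        mirna_shift,
        cfg.mirna_tumor,
        cfg.mirna_normal,
        cfg.expr_noise_sd,
        "MR_T",
        "MR_N",
        mirna_ids,
        "mirna",
    )
    mirna_design = SampleDesign(tumor=mr_t, normal=mr_n)

    # target map: planted miRNAs carry the planted MR genes; decoys get
    # random targets
    rng = rngs["targets"]
    target_map: dict[str, set[str]] = {}
    for k in range(n_planted_mirnas):
        chunk = mr_genes[k * cfg.targets_per_mirna : (k + 1) * cfg.targets_per_mirna]
        target_map[mirna_ids[k]] = set(chunk)
    for k in range(n_planted_mirnas, cfg.n_mirnas):
        picks = rng.choice(cfg.n_genes, size=cfg.targets_per_mirna, replace=False)
        target_map[mirna_ids[k]] = {gene_ids[i] for i in picks}

    # mutations
    maf_calls, case_samples, background_samples = _generate_mutations(
        cfg, rngs["mutation"], gene_ids, plan["GM"]
    )

    # ground truth
    truth = SyntheticTruth(
        planted={
            "GE": {gene_ids[i]: cfg.ge_fold for i in plan["GE"]},
            "CN": {gene_ids[i]: cfg.cn_copy / 2.0 for i in plan["CN"]},
            "ME": {gene_ids[i]: cfg.me_delta for i in plan["ME"]},
            "MR": {gene_ids[i]: cfg.mirna_fold for i in plan["MR"]},
            "GM": {gene_ids[i]: cfg.mut_rate_case for i in plan["GM"]},
        },
        planted_mirnas={
            mirna_ids[k]: cfg.mirna_fold for k in range(n_planted_mirnas)
        },
        expected_level={
            gene_ids[i]: 1
            + sum(i in set(plan[m]) for m in ("CN", "ME", "MR", "GM"))
            for i in plan["GE"]
        },
    )
    return Study(
        config=cfg,
        gene_ids=gene_ids,
        gene_model=gene_model,
        expression=expr,
        expression_design=expr_design,
        segments=segments,
        cnv_design=cnv_design,
        beta_a=beta_a,
        probe_map_a=probe_map_a,
        design_a=design_a,
        beta_b=beta_b,
        probe_map_b=probe_map_b,
        design_b=design_b,
        mirna=mirna,
        mirna_design=mirna_design,
        target_map=target_map,
        maf_calls=maf_calls,
        case_samples=case_samples,
        background_samples=background_samples,
        truth=truth,
    )


STUDY_FILES = {
    "expression": "expression.tsv",
    "expression_design": "expression_design.tsv",
    "segments": "segments.seg",
    "cnv_design": "cnv_design.tsv",
    "gene_model": "genes.bed",
    "beta_a": "beta_hm27.tsv",
    "probe_map_a": "probe_map_hm27.tsv",
    "design_a": "design_hm27.tsv",
    "beta_b": "beta_hm450.tsv",
    "probe_map_b": "probe_map_hm450.tsv",
    "design_b": "design_hm450.tsv",
    "mirna": "mirna.tsv",
    "mirna_design": "mirna_design.tsv",
    "target_map": "target_map.tsv",
    "maf": "mutations.maf",
    "case_samples": "case_samples.txt",
    "background_samples": "background_samples.txt",
    "truth": "truth.tsv",
    "expected_levels": "expected_levels.tsv",
    "manifest": "manifest.json",
}


def write_study(study: Study, directory: str | Path, overwrite: bool = False) -> Path:
    """Write every study input (and the truth tables) to ``directory``."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    f = {k: directory / v for k, v in STUDY_FILES.items()}
    iof.write_matrix(study.expression, f["expression"])
    iof.write_design(study.expression_design, f["expression_design"])
    iof.write_seg(study.segments, f["segments"])
    iof.write_design(study.cnv_design, f["cnv_design"])
    iof.write_gene_model(study.gene_model, f["gene_model"])
    iof.write_matrix(study.beta_a, f["beta_a"])
    iof.write_probe_map(study.probe_map_a, f["probe_map_a"])
    iof.write_design(study.design_a, f["design_a"])
    iof.write_matrix(study.beta_b, f["beta_b"])
    iof.write_probe_map(study.probe_map_b, f["probe_map_b"])
    iof.write_design(study.design_b, f["design_b"])
    iof.write_matrix(study.mirna, f["mirna"])
    iof.write_design(study.mirna_design, f["mirna_design"])
    iof.write_target_map(study.target_map, f["target_map"])
    iof.write_maf(study.maf_calls, f["maf"])
    with f["case_samples"].open("w") as fh:
        fh.writelines(s + "\n" for s in study.case_samples)
    with f["background_samples"].open("w") as fh:
        fh.writelines(s + "\n" for s in study.background_samples)
    with f["truth"].open("w") as fh:
        fh.write("modality\tfeature_id\teffect\n")
        for modality in sorted(study.truth.planted):
            for fid in sorted(study.truth.planted[modality]):
                fh.write(
                    f"{modality}\t{fid}\t{study.truth.planted[modality][fid]:.6g}\n"
                )
        for mid in sorted(study.truth.planted_mirnas):
            fh.write(f"MIRNA\t{mid}\t{study.truth.planted_mirnas[mid]:.6g}\n")
    with f["expected_levels"].open("w") as fh:
        fh.write("gene_id\texpected_level\n")
        for gid in sorted(study.truth.expected_level):
            fh.write(f"{gid}\t{study.truth.expected_level[gid]}\n")
    manifest = {
        "files": sorted(v for k, v in STUDY_FILES.items() if k != "manifest"),
        "config": asdict(study.config),
    }
    with f["manifest"].open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory


@dataclass
class StudyFiles:
    """On-disk study loaded back through the io_formats readers."""

    expression: OmicsMatrix
    expression_design: SampleDesign
    segments: list[SegmentRecord]
    cnv_design: SampleDesign
    gene_model: list[GeneModel]
    beta_a: OmicsMatrix
    probe_map_a: dict[str, str]
    design_a: SampleDesign
    beta_b: OmicsMatrix
    probe_map_b: dict[str, str]
    design_b: SampleDesign
    mirna: OmicsMatrix
    mirna_design: SampleDesign
    target_map: dict[str, set[str]]
    maf_calls: list[MutationCall]
    case_samples: list[str]
    background_samples: list[str]
    truth: SyntheticTruth


def read_study(directory: str | Path) -> StudyFiles:
    directory = Path(directory)
    f = {k: directory / v for k, v in STUDY_FILES.items()}
    truth = SyntheticTruth()
    if f["truth"].exists():
        df = pd.read_csv(f["truth"], sep="\t", dtype={"feature_id": str})
        for modality, grp in df.groupby("modality"):
            entries = dict(zip(grp["feature_id"], grp["effect"].astype(float)))
            if modality == "MIRNA":
                truth.planted_mirnas = entries
            else:
                truth.planted[str(modality)] = entries
    if f["expected_levels"].exists():
        df = pd.read_csv(f["expected_levels"], sep="\t", dtype={"gene_id": str})
        truth.expected_level = dict(
            zip(df["gene_id"], df["expected_level"].astype(int))
        )
    return StudyFiles(
        expression=iof.read_matrix(f["expression"], "expression"),
        expression_design=iof.read_design(f["expression_design"]),
        segments=iof.read_seg(f["segments"]),
        cnv_design=iof.read_design(f["cnv_design"]),
        gene_model=iof.read_gene_model(f["gene_model"]),
        beta_a=iof.read_matrix(f["beta_a"], "beta"),
        probe_map_a=iof.read_probe_map(f["probe_map_a"]),
        design_a=iof.read_design(f["design_a"]),
        beta_b=iof.read_matrix(f["beta_b"], "beta"),
        probe_map_b=iof.read_probe_map(f["probe_map_b"]),
        design_b=iof.read_design(f["design_b"]),
        mirna=iof.read_matrix(f["mirna"], "mirna"),
        mirna_design=iof.read_design(f["mirna_design"]),
        target_map=iof.read_target_map(f["target_map"]),
        maf_calls=iof.read_maf(f["maf"]),
        case_samples=sorted(iof.read_gene_list(f["case_samples"])),
        background_samples=sorted(iof.read_gene_list(f["background_samples"])),
        truth=truth,
    )
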