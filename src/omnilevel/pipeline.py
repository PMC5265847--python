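"""End-to-end orchestration: five screens -> evidence levels -> enrichment.

`run_study` works on any object exposing the study attributes (an in-memory
`simulate.Study` or an on-disk `simulate.StudyFiles`); the CLI wraps it with
file I/O and a run manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io_formats as iof
from .enrichment import DEFAULT_ENRICH_FDR, enrich
from .integration import (
    assign_levels,
    build_evidence_table,
    level_counts,
    level_members,
    overlap_counts,
)
from .screens import (
    build_mutation_matrix,
    collapse_probes_to_genes,
    map_mirna_targets,
    map_segments_to_genes,
    screen_copy_number,
    screen_expression,
    screen_methylation,
    screen_mirna,
    screen_mutations,
)
from .types import ScreenResult, ThresholdConfig

logger = logging.getLogger("omnilevel")


@dataclass
class PipelineResult:
    screens: dict[str, ScreenResult]
    mirna_screen: ScreenResult
    mr_genes: set[str]
    evidence: pd.DataFrame
    levels: pd.Series
    level_counts: dict[int, int]
    level_members: dict[int, list[str]]
    overlaps: dict[tuple[str, ...], int]
    universe: set[str]
    enrichment: pd.DataFrame | None = None
    stage_rows: dict[str, int] = field(default_factory=dict)


def run_study(
    study,
    cfg: ThresholdConfig | None = None,
    gene_sets: Mapping[str, set[str]] | None = None,
    enrich_query_level: int = 2,
    enrich_fdr: float = DEFAULT_ENRICH_FDR,
    classification_filter: str = "nonsilent",
) -> PipelineResult:
    """Run every screen and the evidence integration on a study.

    ``gene_sets`` (a GMT-style mapping) triggers the optional overlap
    enrichment of the nested Level-``enrich_query_level`` gene list against
    the universe of genes tested in the expression screen.
    """
    cfg = cfg or ThresholdConfig()
    timings: dict[str, float] = {}

    def _stage(name: str):
        timings[name] = time.perf_counter()

    _stage("GE")
    ge = screen_expression(study.expression, study.expression_design, cfg)

    _stage("CN")
    copies = map_segments_to_genes(
        study.segments,
        study.gene_model,
        samples=study.cnv_design.tumor + study.cnv_design.normal,
        weighting=cfg.segment_weighting,
    )
    cn = screen_copy_number(copies, study.cnv_design, cfg)

    _stage("ME")
    gene_beta_a = collapse_probes_to_genes(study.beta_a, study.probe_map_a)
    gene_beta_b = collapse_probes_to_genes(study.beta_b, study.probe_map_b)
    me = screen_methylation(
        gene_beta_a, gene_beta_b, study.design_a, study.design_b, cfg
    )

    _stage("MR")
    mirna_screen = screen_mirna(study.mirna, study.mirna_design, cfg)
    mr_genes = map_mirna_targets(mirna_screen.called_set, study.target_map)
    mr = _mr_gene_result(mr_genes, mirna_screen)

    _stage("GM")
    background = build_mutation_matrix(
        study.maf_calls, study.background_samples, classification_filter
    )
    case = build_mutation_matrix(
        study.maf_calls, study.case_samples, classification_filter
    )
    gm = screen_mutations(case, background, cfg)

    _stage("integrate")
    evidence = build_evidence_table(
        ge.called_set, cn.called_set, me.called_set, mr_genes, gm.called_set
    )
    levels = assign_levels(evidence)
    screens = {"GE": ge, "CN": cn, "ME": me, "MR": mr, "GM": gm}
    universe = ge.tested_set

    result = PipelineResult(
        screens=screens,
        mirna_screen=mirna_screen,
        mr_genes=mr_genes,
        evidence=evidence,
        levels=levels,
        level_counts=level_counts(evidence),
        level_members=level_members(evidence),
        overlaps=overlap_counts(evidence),
        universe=universe,
        stage_rows={m: len(s.table) for m, s in screens.items()},
    )
    if gene_sets:
        _stage("enrich")
        query = set(result.level_members.get(enrich_query_level, [])) & universe
        if query:
            result.enrichment = enrich(
                query, gene_sets, universe, fdr_threshold=enrich_fdr
            )
        else:
            logger.warning(
                "enrichment skipped: empty Level-%d query", enrich_query_level
            )
    order = list(timings)
    for name, nxt in zip(order, order[1:]):
        logger.info("stage %s: %.2fs", name, timings[nxt] - timings[name])
    return result


def _mr_gene_result(mr_genes: set[str], mirna_screen: ScreenResult) -> ScreenResult:
    """Wrap the MR gene set as a ScreenResult for uniform reporting.

    The per-gene MR evidence is a set membership (targets of called miRNAs),
    so the statistical columns are blank at gene level; the underlying
    per-miRNA statistics live in the miRNA screen table.
    """
    genes = sorted(mr_genes)
    table = pd.DataFrame(
        {
            "effect": float("nan"),
            "p": float("nan"),
            "q": float("nan"),
            "tested": True,
            "called": True,
        },
        index=pd.Index(genes, name="feature_id"),
    )
    return ScreenResult(
        modality="MR",
        table=table,
        n_case=mirna_screen.n_case,
        n_comparison=mirna_screen.n_comparison,
    )


OUTPUT_FILES = {
    "GE": "screen_GE.tsv",
    "CN": "screen_CN.tsv",
    "ME": "screen_ME.tsv",
    "GM": "screen_GM.tsv",
    "mirna": "screen_MR_mirna.tsv",
    "mr_genes": "screen_MR_genes.txt",
    "evidence": "evidence_table.tsv",
    "levels": "levels.tsv",
    "level_counts": "level_counts.tsv",
    "overlaps": "overlap_counts.tsv",
    "enrichment": "enrichment.tsv",
    "heatmap": "evidence_level3.tsv",
    "manifest": "manifest.json",
}


def write_results(
    result: PipelineResult,
    directory: str | Path,
    cfg: ThresholdConfig,
    config_text: str | None = None,
) -> Path:
    """Write every pipeline output deterministically, plus a run manifest."""
    from . import __version__
    from .integration import evidence_heatmap_export

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = {k: directory / v for k, v in OUTPUT_FILES.items()}
    for modality in ("GE", "CN", "ME", "GM"):
        iof.write_screen_result(result.screens[modality], f[modality])
    iof.write_screen_result(result.mirna_screen, f["mirna"])
    iof.write_gene_list(result.mr_genes, f["mr_genes"])
    iof.write_evidence_table(result.evidence, f["evidence"])
    with f["levels"].open("w") as fh:
        fh.write("gene_id\tlevel\n")
        for gene in sorted(result.levels.index):
            fh.write(f"{gene}\t{int(result.levels[gene])}\n")
    with f["level_counts"].open("w") as fh:
        fh.write("level\tn_genes\n")
        for k in sorted(result.level_counts):
            fh.write(f"{k}\t{result.level_counts[k]}\n")
    with f["overlaps"].open("w") as fh:
        fh.write("modalities\tn_genes\n")
        for combo in sorted(result.overlaps):
            fh.write("+".join(combo) + f"\t{result.overlaps[combo]}\n")
    evidence_heatmap_export(result.evidence, min_level=3, path=f["heatmap"])
    if result.enrichment is not None:
        result.enrichment.to_csv(
            f["enrichment"], sep="\t", index=False, float_format="%.6g"
        )
    manifest = {
        "version": __version__,
        "thresholds": vars(cfg),
        "config_sha256": hashlib.sha256(
            (config_text or "").encode()
        ).hexdigest(),
        "stage_rows": result.stage_rows,
        "n_called": {m: s.n_called for m, s in result.screens.items()},
        "level_counts": {str(k): v for k, v in result.level_counts.items()},
    }
    with f["manifest"].open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory
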