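"""Readers and writers for every external format the pipeline touches.

Formats: SEG (segmented copy number), MAF (somatic mutation calls), plain TSV
matrices, BED gene models, GMT gene-set collections, two-column maps
(miRNA->target, probe->gene), sample-design tables, and the result tables the
pipeline emits.  Writers are byte-deterministic (fixed column order,
6-significant-digit floats, sorted rows) so outputs diff cleanly.

Internal genomic coordinates are 1-based inclusive; BED's 0-based half-open
coordinates are converted at this boundary (start+1, end) and back on write.
Chromosome names are taken verbatim (no "chr" normalization).
"""
from __future__ import annotations

import csv
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    MODALITIES,
    GeneModel,
    MutationCall,
    OmicsMatrix,
    SampleDesign,
    ScreenResult,
    SegmentRecord,
)

logger = logging.getLogger("omnilevel")

NA_TOKENS = ["NA", "NaN", "nan", "null", ""]
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return FLOAT_FMT % x


def _norm_col(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


_SEG_ALIASES = {
    "sample": {"sample", "sampleid", "id"},
    "chrom": {"chromosome", "chrom", "chr"},
    "start": {"start", "locstart", "startposition"},
    "end": {"end", "locend", "endposition"},
    "seg_value": {"segmentmean", "segmean", "mean", "value"},
}


def _resolve_seg_columns(columns: Sequence[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    normed = {_norm_col(c): c for c in columns}
    for key, aliases in _SEG_ALIASES.items():
        hit = [col for norm, col in normed.items() if norm in aliases]
        if not hit:
            raise FormatError(f"SEG file missing required column for {key!r}")
        resolved[key] = hit[0]
    return resolved


def read_seg(path: str | Path) -> list[SegmentRecord]:
    """Read a tab-delimited SEG file into SegmentRecords (1-based inclusive).

    Validates coordinates and checks that segments of one sample do not
    overlap on the same chromosome.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    cols = _resolve_seg_columns(df.columns)
    records: list[SegmentRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = dict(zip(df.columns, row))
        try:
            start = int(raw[cols["start"]])
            end = int(raw[cols["end"]])
            value = float(raw[cols["seg_value"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: non-numeric coordinate or value") from exc
        try:
            records.append(
                SegmentRecord(
                    sample_id=str(raw[cols["sample"]]),
                    chrom=str(raw[cols["chrom"]]),
                    start=start,
                    end=end,
                    seg_value=value,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    _check_segment_overlaps(records, path)
    return records


def _check_segment_overlaps(records: Sequence[SegmentRecord], path: Path) -> None:
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.chrom), []).append(rec)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start <= prev.end:
                raise FormatError(
                    f"{path}: overlapping segments for sample {sample} on "
                    f"{chrom}: {prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )


def write_seg(records: Iterable[SegmentRecord], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(records, key=lambda r: (r.sample_id, r.chrom, r.start))
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Sample", "Chromosome", "Start", "End", "Segment_Mean"])
        for r in rows:
            w.writerow([r.sample_id, r.chrom, r.start, r.end, _fmt(r.seg_value)])


MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(path: str | Path) -> list[MutationCall]:
    """Read a MAF file; duplicates are preserved (dedup happens downstream)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: MAF missing required column {col!r}")
    calls: list[MutationCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        gene = raw["Hugo_Symbol"]
        sample = raw["Tumor_Sample_Barcode"]
        if gene is None or (isinstance(gene, float) and math.isnan(gene)) or gene == "":
            raise FormatError(f"{path}: row {i}: empty Hugo_Symbol")
        if (
            sample is None
            or (isinstance(sample, float) and math.isnan(sample))
            or sample == ""
        ):
            raise FormatError(f"{path}: row {i}: empty Tumor_Sample_Barcode")
        vc = raw["Variant_Classification"]
        if vc is None or (isinstance(vc, float) and math.isnan(vc)):
            vc = ""
        calls.append(MutationCall(str(gene), str(sample), str(vc)))
    return calls


def write_maf(calls: Iterable[MutationCall], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(
        calls, key=lambda c: (c.gene_id, c.sample_id, c.variant_classification)
    )
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MAF_REQUIRED)
        for c in rows:
            w.writerow([c.gene_id, c.sample_id, c.variant_classification])


def read_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a features-x-samples TSV matrix of the declared kind.

    First column holds feature IDs; NA tokens become missing values.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature IDs: {dups[:5]}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric matrix value: {exc}") from exc
    try:
        return OmicsMatrix(df, kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.data
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", *df.columns])
        vals = df.to_numpy()
        for fid, row in zip(df.index, vals):
            w.writerow([fid, *[_fmt(v) for v in row]])


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read a BED-like gene model (chrom, start0, end, gene_id[, score, strand]).

    BED half-open 0-based coordinates become the internal 1-based inclusive
    convention: (start+1, end).
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {i}: BED needs >= 4 fields")
            chrom, s, e, gene_id = fields[:4]
            try:
                start0, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinate") from exc
            if start0 < 0 or start0 >= end:
                raise FormatError(
                    f"{path}: line {i}: invalid BED interval {start0}-{end}"
                )
            if gene_id in seen:
                raise FormatError(f"{path}: line {i}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            genes.append(GeneModel(gene_id, chrom, start0 + 1, end, strand))
    return genes


def write_gene_model(genes: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with path.open("w", newline="") as fh:
        for g in rows:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members per line."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {i}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"{path}: line {i}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for name in sorted(sets):
            members = sorted(set(sets[name]))
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_two_column_map(
    path: str | Path, key_name: str = "key", value_name: str = "value"
) -> list[tuple[str, str]]:
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {i}: expected two tab-separated fields")
            k, v = fields[0], fields[1]
            if i == 1 and _norm_col(k) in {
                _norm_col(key_name),
                "mirnaid",
                "mirna",
                "probeid",
                "probe",
            }:
                continue  # header row
            if not k:
                raise FormatError(f"{path}: line {i}: empty {key_name}")
            pairs.append((k, v))
    return pairs


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (mirna_id, gene_id) TSV into a target map."""
    mapping: dict[str, set[str]] = {}
    for mirna, gene in read_two_column_map(path, "mirna_id", "gene_id"):
        mapping.setdefault(mirna, set())
        if gene:
            mapping[mirna].add(gene)
    return mapping


def write_target_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mirna in sorted(mapping):
            for gene in sorted(set(mapping[mirna])):
                fh.write(f"{mirna}\t{gene}\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_id) TSV."""
    mapping: dict[str, str] = {}
    for probe, gene in read_two_column_map(path, "probe_id", "gene_id"):
        mapping[probe] = gene
    return mapping


def write_probe_map(mapping: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("probe_id\tgene_id\n")
        for probe in sorted(mapping):
            fh.write(f"{probe}\t{mapping[probe]}\n")


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design TSV (sample_id, group[, pair_id])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=NA_TOKENS, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: design missing column {col!r}")
    tumor = [
        str(s) for s, g in zip(df["sample_id"], df["group"]) if str(g).lower() == "tumor"
    ]
    normal = [
        str(s) for s, g in zip(df["sample_id"], df["group"]) if str(g).lower() == "normal"
    ]
    bad = set(df["group"].astype(str).str.lower()) - {"tumor", "normal"}
    if bad:
        raise FormatError(f"{path}: unknown group labels {sorted(bad)}")
    pairs = None
    if "pair_id" in df.columns and df["pair_id"].astype(str).str.len().gt(0).any():
        by_pair: dict[str, dict[str, str]] = {}
        for s, g, pid in zip(df["sample_id"], df["group"], df["pair_id"]):
            pid = str(pid)
            if not pid or pid.lower() in ("na", "nan"):
                continue
            by_pair.setdefault(pid, {})[str(g).lower()] = str(s)
        pairs = [
            (d["tumor"], d["normal"])
            for pid, d in sorted(by_pair.items())
            if "tumor" in d and "normal" in d
        ]
    try:
        return SampleDesign(tumor=tumor, normal=normal, pairs=pairs)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_design(design: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    pair_of: dict[str, str] = {}
    if design.pairs:
        for i, (t, n) in enumerate(design.pairs):
            pair_of[t] = f"P{i:04d}"
            pair_of[n] = f"P{i:04d}"
    with path.open("w", newline="") as fh:
        fh.write("sample_id\tgroup\tpair_id\n")
        for s in design.tumor:
            fh.write(f"{s}\ttumor\t{pair_of.get(s, '')}\n")
        for s in design.normal:
            fh.write(f"{s}\tnormal\t{pair_of.get(s, '')}\n")


def write_screen_result(result: ScreenResult, path: str | Path) -> None:
    """Write a screen result TSV, rows sorted by (q, p, feature_id)."""
    path = Path(path)
    df = result.table.copy()
    df.index.name = "feature_id"
    sort_q = df["q"].fillna(np.inf)
    sort_p = df["p"].fillna(np.inf)
    order = sorted(
        range(len(df)), key=lambda i: (sort_q.iloc[i], sort_p.iloc[i], df.index[i])
    )
    df = df.iloc[order]
    cols = list(df.columns)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(["feature_id", *cols]) + "\n")
        for fid, row in df.iterrows():
            out = [str(fid)]
            for col in cols:
                v = row[col]
                if isinstance(v, (bool, np.bool_)):
                    out.append("1" if v else "0")
                elif isinstance(v, (int, np.integer)):
                    out.append(str(int(v)))
                elif isinstance(v, (float, np.floating)):
                    out.append(_fmt(float(v)))
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


def read_screen_result(path: str | Path, modality: str) -> ScreenResult:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    for col in ("effect", "p", "q", "tested", "called"):
        if col not in df.columns:
            raise FormatError(f"{path}: screen result missing column {col!r}")
    df["tested"] = df["tested"].astype(int).astype(bool)
    df["called"] = df["called"].astype(int).astype(bool)
    for col in ("effect", "p", "q"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_case = int(df["n_case"].max()) if "n_case" in df.columns and len(df) else 0
    n_comp = (
        int(df["n_comparison"].max()) if "n_comparison" in df.columns and len(df) else 0
    )
    return ScreenResult(modality=modality, table=df, n_case=n_case, n_comparison=n_comp)


def write_evidence_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x {GE,CN,ME,MR,GM} boolean table as 0/1 TSV."""
    path = Path(path)
    table = table.loc[sorted(table.index), list(MODALITIES)]
    with path.open("w", newline="") as fh:
        fh.write("\t".join(["gene_id", *MODALITIES]) + "\n")
        for gene, row in table.iterrows():
            fh.write("\t".join([str(gene), *["1" if row[m] else "0" for m in MODALITIES]]) + "\n")


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [m for m in MODALITIES if m not in df.columns]
    if missing:
        raise FormatError(f"{path}: evidence table missing columns {missing}")
    return df[list(MODALITIES)].astype(int).astype(bool)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    path = Path(path)
    with path.open() as fh:
        return {line.strip() for line in fh if line.strip()}
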