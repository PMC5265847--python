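"""Evidence integration: fuse the five called gene sets into evidence levels.

A gene enters the scheme only if it passed the expression screen (GE); its
level is 1 plus the number of other modalities (CN, ME, MR, GM) that also
called it.  Levels are nested: a Level-3 gene is also a member of Levels 1
and 2, and reported level counts follow that nesting
(count at level k = #{g in GE with other-modality evidence >= k-1}), so the
counts are monotone non-increasing in k.
"""
from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import MODALITIES

OTHER_MODALITIES = ("CN", "ME", "MR", "GM")
MAX_LEVEL = 5


def build_evidence_table(
    ge: Iterable[str],
    cn: Iterable[str],
    me: Iterable[str],
    mr: Iterable[str],
    gm: Iterable[str],
) -> pd.DataFrame:
    """Gene x {GE, CN, ME, MR, GM} boolean table over the union of the sets."""
    sets = dict(zip(MODALITIES, (set(ge), set(cn), set(me), set(mr), set(gm))))
    genes = sorted(set().union(*sets.values()))
    return pd.DataFrame(
        {m: [g in sets[m] for g in genes] for m in MODALITIES},
        index=pd.Index(genes, name="gene_id"),
    )


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [m for m in MODALITIES if m not in table.columns]
    if missing:
        raise ValueError(f"evidence table missing modality columns {missing}")
    return table[list(MODALITIES)].astype(bool)


def assign_levels(table: pd.DataFrame) -> pd.Series:
    """Highest (exact) evidence level per GE gene: 1 + #other-modality calls.

    Genes without GE evidence are excluded (the Level-1 gate).
    """
    table = _check_table(table)
    ge = table[table["GE"]]
    levels = 1 + ge[list(OTHER_MODALITIES)].sum(axis=1)
    return levels.astype(int).rename("level")


def level_members(table: pd.DataFrame) -> dict[int, list[str]]:
    """Nested membership lists: level k holds every GE gene with >= k-1 other calls."""
    levels = assign_levels(table)
    return {
        k: sorted(levels.index[levels >= k]) for k in range(1, MAX_LEVEL + 1)
    }


def level_counts(table: pd.DataFrame) -> dict[int, int]:
    """Nested level counts; monotone non-increasing in k by construction."""
    return {k: len(v) for k, v in level_members(table).items()}


def overlap_counts(
    table: pd.DataFrame,
    combos: Sequence[Sequence[str]] | None = None,
) -> dict[tuple[str, ...], int]:
    """Inclusive intersection sizes for the requested modality subsets.

    Default combos: every pair containing GE and every triple containing GE.
    Counts are inclusive (genes true on ALL modalities of the subset), not
    exclusive Venn regions.
    """
    table = _check_table(table)
    if combos is None:
        others = OTHER_MODALITIES
        combos = [("GE", m) for m in others] + [
            ("GE", a, b) for a, b in combinations(others, 2)
        ]
    out: dict[tuple[str, ...], int] = {}
    for combo in combos:
        combo = tuple(combo)
        unknown = [m for m in combo if m not in MODALITIES]
        if unknown:
            raise ValueError(f"unknown modalities in combo: {unknown}")
        mask = table[list(combo)].all(axis=1)
        out[combo] = int(mask.sum())
    return out


def evidence_heatmap_export(
    table: pd.DataFrame,
    min_level: int = 3,
    path=None,
    plot_path=None,
) -> pd.DataFrame:
    """0/1 evidence matrix for genes at or above ``min_level``.

    Rows are sorted by descending exact level then gene ID.  Optionally
    writes a TSV and/or renders a heatmap (rendering is non-normative and
    needs matplotlib).
    """
    table = _check_table(table)
    levels = assign_levels(table)
    keep = levels.index[levels >= min_level]
    sub = table.loc[keep].astype(int)
    order = sorted(keep, key=lambda g: (-int(levels[g]), g))
    sub = sub.loc[order]
    sub.index.name = "gene_id"
    if path is not None:
        from .io_formats import write_evidence_table

        write_evidence_table(sub.astype(bool), path)
    if plot_path is not None and len(sub):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(4, max(2, 0.25 * len(sub))), constrained_layout=True
        )
        ax.imshow(sub.to_numpy(), cmap="Greys", aspect="auto", vmin=0, vmax=1)
        ax.set_xticks(range(len(sub.columns)), sub.columns)
        ax.set_yticks(range(len(sub)), sub.index, fontsize=6)
        ax.set_title(f"Evidence for Level >= {min_level} genes")
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return sub


def evidence_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene exact level plus modality flags, sorted by level then gene."""
    table = _check_table(table)
    levels = assign_levels(table)
    out = table.loc[sorted(levels.index)].astype(int)
    out["level"] = levels
    return out.sort_values("level", ascending=False, kind="stable")
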