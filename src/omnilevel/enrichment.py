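"""Gene-set overlap enrichment: hypergeometric tail per set, BH FDR across sets.

Each candidate set is intersected with the universe before testing, so genes
outside the universe can never change a set's p-value.  The default
significance filter (FDR < 1e-10) marks the reported sets; all sets remain in
the output table.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .stats_core import bh_fdr, hypergeometric_overlap

DEFAULT_ENRICH_FDR = 1e-10


def enrich(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_threshold: float = DEFAULT_ENRICH_FDR,
) -> pd.DataFrame:
    """Hypergeometric overlap of ``query`` with every set in ``collection``.

    Returns a table (set_name, set_size, overlap, p, q, significant) sorted
    by (q, set_name).  ``query`` must be a subset of ``universe``.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query:
        raise ValueError("query must be non-empty")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query contains {len(stray)} genes outside the universe "
            f"(e.g. {sorted(stray)[:3]})"
        )
    names = sorted(collection)
    rows = []
    for name in names:
        members = set(collection[name]) & universe
        overlap = len(members & query)
        p = (
            hypergeometric_overlap(len(universe), len(members), len(query), overlap)
            if members
            else 1.0
        )
        rows.append((name, len(members), overlap, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < fdr_threshold
    df = df.sort_values(["q", "set_name"], kind="stable").reset_index(drop=True)
    return df
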