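"""Drug–gene actionability filtering.

Survival-relevant genes are only useful therapeutic leads if something can
plausibly target them.  This stage joins a candidate gene list against a
frozen snapshot of a drug–gene interaction database (DGIdb-style TSV with
``gene``, ``category``, ``source`` and ``interaction_type`` columns; the live
database is versioned and unstable, so a user-supplied snapshot keeps runs
reproducible).  A gene is *potentially actionable* when at least one snapshot
row matches its symbol — druggable-category rows and interaction-claim rows
both count.  Matching is by upper-cased symbol only; an alias map can be
supplied but none ships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DruggabilityTable", "load_druggability_table", "filter_actionable"]

_REQUIRED = ["gene", "category", "source", "interaction_type"]


@dataclass
class DruggabilityTable:
    """Deduplicated, symbol-normalized drug–gene interaction snapshot."""

    entries: pd.DataFrame

    def genes(self) -> set:
        return set(self.entries["gene"])


def load_druggability_table(source, alias_map=None) -> DruggabilityTable:
    """Read a druggability snapshot TSV (path or file-like).

    Gene symbols are upper-cased; fully duplicate rows are dropped; extra
    columns are ignored.  `alias_map` (dict alias -> canonical symbol)
    rewrites symbols before normalization.
    """
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"druggability table missing required column(s): {missing}")
    df = df[_REQUIRED].copy()
    if alias_map:
        df["gene"] = df["gene"].map(lambda g: alias_map.get(g, g))
    df["gene"] = df["gene"].str.upper()
    before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    logger.info("druggability table: %d rows (%d duplicates removed), %d genes",
                len(df), before - len(df), df["gene"].nunique())
    return DruggabilityTable(entries=df)


def filter_actionable(genes: Sequence[str], table: DruggabilityTable):
    """Keep genes with >= 1 snapshot entry; returns (subset, evidence frame).

    Input order is preserved; the filter is idempotent and its output is a
    subset of its input.  Matching is case-insensitive on the symbol.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    known = table.genes()
    actionable = [g for g in genes if g.upper() in known]
    evidence = table.entries[table.entries["gene"].isin({g.upper() for g in actionable})]
    evidence = evidence.set_index("gene").loc[
        [g.upper() for g in actionable]].reset_index()
    return actionable, evidence
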