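"""Promoter chromatin-state classification and lineage-resolved bivalency.

A promoter is *bivalent* in a cell type when statistically enriched
islands of both H3K4me3 and H3K27me3 overlap the window within 500 bp of
the TSS ([TSS-500, TSS+500], i.e. [TSS-500, TSS+501) in half-open
coordinates).  States form the four-way partition
{bivalent, K4_only, K27_only, none}.  Along a lineage tree, a parent's
bivalent promoters either remain bivalent in a child or *resolve* by
losing one or both marks; promoters newly bivalent in a child are traced
back to their parent-state *origin*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, overlaps_any

STATES = ("bivalent", "K4_only", "K27_only", "none")

RESOLUTION_CATEGORIES = (
    "remained_bivalent",  # bivalent -> bivalent
    "lost_K27",           # bivalent -> K4_only
    "lost_K4",            # bivalent -> K27_only
    "lost_both",          # bivalent -> none
)

ESTABLISHMENT_CATEGORIES = (
    "had_K4_only",
    "had_K27_only",
    "had_neither",
)

_RESOLUTION_OF = {
    "bivalent": "remained_bivalent",
    "K4_only": "lost_K27",
    "K27_only": "lost_K4",
    "none": "lost_both",
}

_ORIGIN_OF = {
    "K4_only": "had_K4_only",
    "K27_only": "had_K27_only",
    "none": "had_neither",
}


@dataclass(frozen=True)
class LineageTree:
    """A rooted cell-type differentiation tree given as parent->child edges."""

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        children = [c for _, c in self.edges]
        if len(set(children)) != len(children):
            raise ValueError("a cell type may have only one parent")
        roots = set(self.nodes) - set(children)
        if len(roots) != 1:
            raise ValueError(f"lineage must have exactly one root, found {roots}")
        # acyclicity: walking up from any node must terminate
        parent = dict((c, p) for p, c in self.edges)
        for node in self.nodes:
            seen = set()
            while node in parent:
                if node in seen:
                    raise ValueError("lineage tree contains a cycle")
                seen.add(node)
                node = parent[node]

    @property
    def nodes(self) -> tuple[str, ...]:
        out: list[str] = []
        for p, c in self.edges:
            for n in (p, c):
                if n not in out:
                    out.append(n)
        return tuple(out)

    @property
    def root(self) -> str:
        children = {c for _, c in self.edges}
        return next(n for n in self.nodes if n not in children)

    def parent_of(self, node: str) -> str | None:
        for p, c in self.edges:
            if c == node:
                return p
        return None

    def children_of(self, node: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.edges if p == node)


def state_from_marks(k4: bool, k27: bool) -> str:
    if k4 and k27:
        return "bivalent"
    if k4:
        return "K4_only"
    if k27:
        return "K27_only"
    return "none"


def classify_promoter(
    gene: GeneModel,
    k4_islands: pd.DataFrame,
    k27_islands: pd.DataFrame,
    flank: int = 500,
) -> str:
    """State of one promoter from post-FDR island sets of the two marks."""
    win = pd.DataFrame(
        {
            "chrom": [gene.interval.chrom],
            "start": [max(0, gene.tss - flank)],
            "end": [gene.tss + flank + 1],
        }
    )
    k4 = bool(overlaps_any(win, k4_islands)[0]) if not k4_islands.empty else False
    k27 = bool(overlaps_any(win, k27_islands)[0]) if not k27_islands.empty else False
    return state_from_marks(k4, k27)


def promoter_windows(genes: Sequence[GeneModel], flank: int = 500) -> pd.DataFrame:
    """The TSS +/- flank window per gene (both flanks inclusive)."""
    return pd.DataFrame(
        {
            "chrom": [g.interval.chrom for g in genes],
            "start": np.asarray([max(0, g.tss - flank) for g in genes], np.int64),
            "end": np.asarray([g.tss + flank + 1 for g in genes], np.int64),
        },
        index=[g.gene_id for g in genes],
    )


def classify_promoters(
    genes: Sequence[GeneModel],
    k4_islands: pd.DataFrame,
    k27_islands: pd.DataFrame,
    flank: int = 500,
) -> pd.Series:
    """Vectorized state per gene for one cell type."""
    wins = promoter_windows(genes, flank)
    k4 = overlaps_any(wins, k4_islands)
    k27 = overlaps_any(wins, k27_islands)
    states = [state_from_marks(a, b) for a, b in zip(k4, k27)]
    return pd.Series(states, index=wins.index, name="state")


def state_table(
    genes: Sequence[GeneModel],
    islands_by_type: Mapping[str, Mapping[str, pd.DataFrame]],
    flank: int = 500,
) -> pd.DataFrame:
    """Gene x cell-type state table.

    ``islands_by_type[cell_type]`` maps mark name -> post-FDR island frame;
    the marks ``H3K4me3`` and ``H3K27me3`` are used.
    """
    cols = {}
    for cell_type, marks in islands_by_type.items():
        cols[cell_type] = classify_promoters(
            genes, marks["H3K4me3"], marks["H3K27me3"], flank
        )
    return pd.DataFrame(cols)


def resolution_matrix(
    states: pd.DataFrame,
    lineage: LineageTree,
    from_node: str,
    to_nodes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fate counts of ``from_node``-bivalent promoters in each child type.

    Rows are resolution categories; columns are child cell types; each
    column sums to the number of promoters bivalent in ``from_node``.
    """
    if from_node not in states.columns:
        raise KeyError(f"unknown cell type {from_node!r}")
    if to_nodes is None:
        to_nodes = lineage.children_of(from_node)
    to_nodes = list(to_nodes)
    for node in to_nodes:
        if node not in states.columns:
            raise KeyError(f"unknown cell type {node!r}")
    bivalent = states.index[states[from_node] == "bivalent"]
    out = pd.DataFrame(0, index=list(RESOLUTION_CATEGORIES), columns=to_nodes)
    for node in to_nodes:
        fates = states.loc[bivalent, node].map(_RESOLUTION_OF)
        counts = fates.value_counts()
        for cat in RESOLUTION_CATEGORIES:
            out.loc[cat, node] = int(counts.get(cat, 0))
    return out


def establishment_matrix(
    states: pd.DataFrame,
    lineage: LineageTree,
    to_node: str,
) -> pd.Series:
    """Parent-state origins of promoters newly bivalent in ``to_node``."""
    parent = lineage.parent_of(to_node)
    if parent is None:
        raise KeyError(f"{to_node!r} has no parent in the lineage")
    for node in (parent, to_node):
        if node not in states.columns:
            raise KeyError(f"unknown cell type {node!r}")
    newly = states.index[
        (states[to_node] == "bivalent") & (states[parent] != "bivalent")
    ]
    origins = states.loc[newly, parent].map(_ORIGIN_OF)
    counts = origins.value_counts()
    return pd.Series(
        [int(counts.get(cat, 0)) for cat in ESTABLISHMENT_CATEGORIES],
        index=list(ESTABLISHMENT_CATEGORIES),
        name=to_node,
    )


def bivalency_membership_matrix(states: pd.DataFrame) -> pd.DataFrame:
    """Binary gene x cell-type matrix over genes bivalent somewhere.

    Genes (rows) are ordered by descending number of bivalent types, then
    by lexicographic membership pattern, then by gene id — deterministic.
    """
    member = (states == "bivalent")
    member = member.loc[member.any(axis=1)]
    if member.empty:
        return member.astype(int)
    order = sorted(
        member.index,
        key=lambda g: (
            -int(member.loc[g].sum()),
            tuple(~member.loc[g].to_numpy()),
            str(g),
        ),
    )
    return member.loc[order].astype(int)
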