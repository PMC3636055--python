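"""RPKM quantification, pairwise differential expression, type-specific genes.

Differential expression between two libraries uses an exact binomial
split test: conditional on the total count of a gene, the split between
libraries is binomial with success probability given by the library-size
ratio.  This is the exact conditional form of comparing two Poisson
counts.  A gene is called up in A when its log2 fold change (on
library-normalized counts with pseudo-count 1) reaches ``lfc_min`` and
its Benjamini-Hochberg q value is at or below ``fdr_max``.  Downstream
consumers use only the resulting up-sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel
from .core import shifted_positions

logger = logging.getLogger(__name__)


def compute_rpkm(exonic_read_count: int, exon_length: int, library_size: int) -> float:
    """Reads per kb of exon model per million mapped reads."""
    if exon_length < 1:
        raise ValueError("exon length must be >= 1")
    if library_size < 1:
        raise ValueError("library size must be >= 1")
    return exonic_read_count / ((exon_length / 1000.0) * (library_size / 1e6))


def rpkm_table(
    counts: pd.DataFrame, exon_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """RPKM per gene x cell type from a count table (genes x types)."""
    lengths = exon_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths < 1).any():
        raise ValueError("every gene needs an exon length >= 1")
    out = counts.astype(float).copy()
    for col in counts.columns:
        out[col] = counts[col] / (
            (lengths / 1000.0) * (library_sizes[col] / 1e6)
        )
    return out


def count_exonic_reads(
    reads: pd.DataFrame, genes: list[GeneModel], shift: int = 0
) -> pd.Series:
    """Reads per gene: a read counts when its (shifted) midpoint-proxy
    position falls in any exon; overlapping genes each count it."""
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=np.int64)
    if reads.empty:
        return counts
    pos = shifted_positions(reads, shift)
    chroms = reads["chrom"].to_numpy()
    by_chrom: dict[str, np.ndarray] = {
        c: np.sort(pos[chroms == c]) for c in np.unique(chroms)
    }
    for g in genes:
        p = by_chrom.get(g.interval.chrom)
        if p is None:
            continue
        n = 0
        for ex in g.exons:
            n += int(
                np.searchsorted(p, ex.end, "left")
                - np.searchsorted(p, ex.start, "left")
            )
        counts[g.gene_id] = n
    return counts


@dataclass(frozen=True)
class DEResult:
    """One ordered pairwise comparison (A, B)."""

    cell_a: str
    cell_b: str
    table: pd.DataFrame  # index gene; columns log2fc, p, q, call
    up_in_a: frozenset[str]
    up_in_b: frozenset[str]


def pairwise_de(
    counts_a: pd.Series,
    counts_b: pd.Series,
    library_a: int,
    library_b: int,
    cell_a: str = "A",
    cell_b: str = "B",
    lfc_min: float = 5.0,
    fdr_max: float = 1e-5,
) -> DEResult:
    """Exact binomial split test plus a log2 fold-change gate."""
    if library_a <= 0 or library_b <= 0:
        raise ValueError("library sizes must be > 0")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count vectors must share one gene universe")
    ca = counts_a.to_numpy(dtype=np.int64)
    cb = counts_b.to_numpy(dtype=np.int64)
    norm_a = (ca + 1) / library_a
    norm_b = (cb + 1) / library_b
    log2fc = np.log2(norm_a / norm_b)
    n = ca + cb
    p0 = library_a / (library_a + library_b)
    # two-sided exact binomial: doubled smaller tail, capped at 1
    lower = stats.binom.cdf(ca, n, p0)
    upper = stats.binom.sf(ca - 1, n, p0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    pvals[n == 0] = 1.0
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    call = np.where(
        (log2fc >= lfc_min) & (qvals <= fdr_max),
        "up_in_a",
        np.where((log2fc <= -lfc_min) & (qvals <= fdr_max), "up_in_b", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": qvals, "call": call},
        index=counts_a.index,
    )
    return DEResult(
        cell_a=cell_a,
        cell_b=cell_b,
        table=table,
        up_in_a=frozenset(table.index[call == "up_in_a"]),
        up_in_b=frozenset(table.index[call == "up_in_b"]),
    )


def all_pairwise_de(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    lfc_min: float = 5.0,
    fdr_max: float = 1e-5,
) -> dict[tuple[str, str], DEResult]:
    """DE for every unordered pair of columns, keyed both ways."""
    results: dict[tuple[str, str], DEResult] = {}
    cols = list(counts.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            res = pairwise_de(
                counts[a], counts[b],
                int(library_sizes[a]), int(library_sizes[b]),
                cell_a=a, cell_b=b, lfc_min=lfc_min, fdr_max=fdr_max,
            )
            results[(a, b)] = res
            results[(b, a)] = DEResult(
                cell_a=b, cell_b=a, table=res.table,
                up_in_a=res.up_in_b, up_in_b=res.up_in_a,
            )
    return results


def type_specific_genes(
    de_results: dict[tuple[str, str], DEResult],
    cell_type: str,
    other_types: list[str],
) -> set[str]:
    """Genes up in ``cell_type`` versus every other type (set intersection)."""
    sets = []
    for other in other_types:
        key = (cell_type, other)
        if key not in de_results:
            raise KeyError(f"missing pairwise comparison {key}")
        sets.append(de_results[key].up_in_a)
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def group_by_expression(rpkm: pd.Series, n_groups: int = 200) -> pd.Series:
    """Sort genes descending by RPKM and split into near-equal groups.

    Group 0 holds the most highly expressed genes; ties break by gene
    identifier so the grouping is deterministic.  Group sizes differ by at
    most one.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if len(rpkm) < n_groups:
        logger.warning(
            "fewer genes (%d) than groups (%d): groups of size <= 1",
            len(rpkm), n_groups,
        )
    order = rpkm.to_frame("rpkm")
    order["gene"] = order.index
    order = order.sort_values(["rpkm", "gene"], ascending=[False, True])
    groups = pd.Series(0, index=order.index, dtype=np.int64)
    for g, chunk in enumerate(np.array_split(np.arange(len(order)), n_groups)):
        groups.iloc[chunk] = g
    return groups.reindex(rpkm.index)
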