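"""H3K27me3 domain statistics, unification/fragmentation, and clustering.

Broad repressive domains are compared across cell types by uniting each
type's islands into one region set, splitting every united region evenly
into fragments of at most 2 kb, building a fragment x cell-type matrix of
library-normalized read counts, and k-means clustering the fragments.
Also hosts the island size/coverage summaries and the promoter
H3K4me3-consistency vs CpG-island analysis.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import (
    GeneModel,
    GenomeSpec,
    merge_intervals,
    overlaps_any,
    shifted_positions,
    total_length,
)
from .promoters import promoter_windows

logger = logging.getLogger(__name__)


def island_size_stats(islands: pd.DataFrame, bin_width: int = 500) -> dict:
    """Size histogram plus modal/median size and total covered bp.

    The modal size is the midpoint of the most populated size bin.
    """
    if islands.empty:
        raise ValueError("island size statistics need >= 1 island")
    sizes = (islands["end"] - islands["start"]).to_numpy()
    n_bins = int(sizes.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    hist, _ = np.histogram(sizes, bins=edges)
    top = int(hist.argmax())
    return {
        "histogram": hist,
        "bin_edges": edges,
        "density": hist / hist.sum(),
        "modal_size": float(edges[top] + bin_width / 2),
        "median_size": float(np.median(sizes)),
        "total_bp": int(sizes.sum()),
        "n_islands": int(len(sizes)),
    }


def genome_coverage(islands: pd.DataFrame, genome: GenomeSpec) -> float:
    """Fraction of the genome covered by the (merged) island set."""
    if islands.empty:
        return 0.0
    return total_length(merge_intervals(islands)) / genome.total_length


def unify_and_fragment(
    island_sets: Sequence[pd.DataFrame], max_fragment: int = 2000
) -> pd.DataFrame:
    """Unite island sets across cell types and split evenly into fragments.

    Each united region of length L becomes ``n = ceil(L / max_fragment)``
    fragments tiling it left to right, lengths ``floor(L/n)`` or
    ``ceil(L/n)`` (longer ones first), so fragment lengths within one
    region differ by at most 1 bp and sum exactly to L.
    """
    nonempty = [df for df in island_sets if not df.empty]
    if not nonempty:
        return pd.DataFrame(columns=["chrom", "start", "end", "region_id"]).astype(
            {"start": np.int64, "end": np.int64, "region_id": np.int64}
        )
    unified = merge_intervals(pd.concat(nonempty, ignore_index=True))
    rows = []
    for region_id, row in enumerate(unified.itertuples()):
        length = row.end - row.start
        n = -(-length // max_fragment)
        base, rem = divmod(length, n)
        pos = row.start
        for i in range(n):
            frag_len = base + (1 if i < rem else 0)
            rows.append((row.chrom, pos, pos + frag_len, region_id))
            pos += frag_len
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def fragment_read_matrix(
    fragments: pd.DataFrame,
    reads_by_type: Mapping[str, pd.DataFrame],
    library_sizes: Mapping[str, int],
    shift: int = 75,
) -> pd.DataFrame:
    """Fragment x cell-type matrix of reads per 1e7 library reads."""
    mat = pd.DataFrame(index=fragments.index)
    frag_chroms = fragments["chrom"].to_numpy()
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    for cell_type, reads in reads_by_type.items():
        lib = library_sizes[cell_type]
        if lib <= 0:
            raise ValueError(f"zero library size for {cell_type}")
        col = np.zeros(len(fragments))
        if not reads.empty:
            pos = shifted_positions(reads, shift)
            chroms = reads["chrom"].to_numpy()
            for chrom in np.unique(chroms):
                p = np.sort(pos[chroms == chrom])
                mask = frag_chroms == chrom
                lo = np.searchsorted(p, starts[mask], side="left")
                hi = np.searchsorted(p, ends[mask], side="left")
                col[mask] = hi - lo
        mat[cell_type] = col * 1e7 / lib
    return mat


def cluster_fragments(
    matrix: pd.DataFrame, k: int = 20, seed: int = 0
) -> pd.Series:
    """K-means cluster assignments, relabeled by descending read sum.

    Squared-Euclidean k-means with k-means++ initialization, a fixed seed,
    at most 300 iterations, and tolerance 1e-4; cluster labels are then
    permuted so cluster 0 has the largest total read sum.  Deterministic
    for a given seed.
    """
    if matrix.empty:
        raise ValueError("cannot cluster an empty matrix")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of fragments ({len(matrix)})")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10,
        max_iter=300, tol=1e-4, random_state=seed,
    )
    labels = km.fit_predict(matrix.to_numpy())
    sums = pd.Series(matrix.sum(axis=1).to_numpy()).groupby(labels).sum()
    order = sums.sort_values(ascending=False).index.to_numpy()
    relabel = {old: new for new, old in enumerate(order)}
    return pd.Series(
        [relabel[l] for l in labels], index=matrix.index, name="cluster_id"
    )


def h3k4me3_consistency_cpg(
    k4_presence: pd.DataFrame,
    genes: Sequence[GeneModel],
    cpg_islands: pd.DataFrame,
    flank: int = 500,
) -> pd.DataFrame:
    """CpG-island content of consistently vs inconsistently K4me3 promoters.

    ``k4_presence`` is a boolean gene x cell-type frame (H3K4me3 island
    within the promoter window).  Promoters marked in every column form
    the ``consistent`` class; all others are ``other``.  CpG overlap uses
    the same TSS +/- flank window as promoter-state classification.
    """
    wins = promoter_windows(genes, flank)
    has_cpg = pd.Series(overlaps_any(wins, cpg_islands), index=wins.index)
    consistent = k4_presence.all(axis=1)
    rows = []
    for label, mask in (("consistent", consistent), ("other", ~consistent)):
        ids = k4_presence.index[mask]
        n = len(ids)
        n_cpg = int(has_cpg.reindex(ids).sum()) if n else 0
        rows.append((label, n, n_cpg, n_cpg / n if n else float("nan")))
    return pd.DataFrame(
        rows, columns=["class", "n_promoters", "n_with_cpg", "cpg_fraction"]
    ).set_index("class")
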