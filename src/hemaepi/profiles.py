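"""TSS-centered metaprofiles and size-normalized region profiles.

Reads contributing to profiles are optionally restricted to those coming
from statistically enriched islands.  TSS profiles count strand-shifted
read positions in small bins of strand-oriented offset from each TSS
(minus-strand offsets inverted), sum over anchors, smooth with a
centered moving average, and normalize to reads per 1e7 library reads.
Region profiles rescale every region onto a fixed number of equal bins
so regions of different sizes average together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, positions_in_intervals, shifted_positions
from .expression import group_by_expression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileConfig:
    """Binning/smoothing parameters for metaprofiles.

    ``span``: bp profiled on each side of the anchor (6 kb total by
    default).  ``bin``: bin width in bp.  ``smooth_halfwidth``: moving-
    average half-width in bins.  ``shift``: strand-aware read shift in bp
    (half the fragment size).  ``n_region_bins``: bin count for
    size-normalized region profiles.
    """

    span: int = 3000
    bin: int = 10
    smooth_halfwidth: int = 4
    shift: int = 75
    n_region_bins: int = 50
    island_filter: bool = True

    def __post_init__(self) -> None:
        if self.span % self.bin != 0:
            raise ValueError("span must be divisible by bin")
        if self.smooth_halfwidth < 0:
            raise ValueError("smooth_halfwidth must be >= 0")

    @property
    def n_bins(self) -> int:
        return 2 * self.span // self.bin


def filter_reads_to_islands(
    reads: pd.DataFrame, islands: pd.DataFrame, shift: int = 75
) -> pd.DataFrame:
    """Retain reads whose shifted position falls inside any island."""
    if reads.empty:
        return reads
    pos = shifted_positions(reads, shift)
    keep = positions_in_intervals(reads["chrom"].to_numpy(), pos, islands)
    return reads[keep].reset_index(drop=True)


def smooth_truncated(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average; windows shorten at the vector edges."""
    if halfwidth == 0:
        return values.astype(float)
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    lo = np.maximum(np.arange(n) - halfwidth, 0)
    hi = np.minimum(np.arange(n) + halfwidth + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _binned_offsets(
    reads: pd.DataFrame,
    anchors: pd.DataFrame,
    config: ProfileConfig,
) -> np.ndarray:
    """Raw per-bin counts summed over anchors (no smoothing/normalizing).

    ``anchors`` needs columns chrom, pos, strand.  A read near several
    anchors contributes once per anchor.
    """
    counts = np.zeros(config.n_bins, dtype=float)
    if reads.empty or anchors.empty:
        return counts
    pos = shifted_positions(reads, config.shift)
    chroms = reads["chrom"].to_numpy()
    by_chrom = {c: np.sort(pos[chroms == c]) for c in np.unique(chroms)}
    for a in anchors.itertuples():
        p = by_chrom.get(a.chrom)
        if p is None:
            continue
        lo = np.searchsorted(p, a.pos - config.span, side="left")
        hi = np.searchsorted(p, a.pos + config.span, side="left")
        if hi == lo:
            continue
        offsets = p[lo:hi] - a.pos
        if a.strand == "-":
            offsets = -offsets
        idx = (offsets + config.span) // config.bin
        idx = idx[(idx >= 0) & (idx < config.n_bins)]
        counts += np.bincount(idx.astype(np.int64), minlength=config.n_bins)
    return counts


def tss_anchor_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [g.interval.chrom for g in genes],
            "pos": np.asarray([g.tss for g in genes], np.int64),
            "strand": [g.strand for g in genes],
        },
        index=[g.gene_id for g in genes],
    )


def tss_profile(
    reads: pd.DataFrame,
    anchors: pd.DataFrame,
    config: ProfileConfig,
    library_size: int,
    smooth: bool = True,
) -> np.ndarray:
    """Average read-density profile around TSS anchors.

    Per-bin counts over all anchors are smoothed over
    ``2 * smooth_halfwidth + 1`` bins (truncated at the ends) and divided
    by ``library_size / 1e7``.
    """
    if anchors.empty:
        raise ValueError("TSS profile needs >= 1 anchor")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    counts = _binned_offsets(reads, anchors, config)
    if smooth:
        counts = smooth_truncated(counts, config.smooth_halfwidth)
    return counts / (library_size / 1e7)


def expression_sorted_tss_matrix(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    rpkm: pd.Series,
    config: ProfileConfig,
    library_size: int,
    n_groups: int = 200,
    smooth: bool = False,
) -> pd.DataFrame:
    """Group x bin matrix of TSS profiles, rows ordered by expression rank.

    Genes are sorted into ``n_groups`` near-equal groups by descending
    RPKM; row g is the profile over group g's TSSs (group 0 = most
    expressed).
    """
    anchors = tss_anchor_frame(genes)
    groups = group_by_expression(rpkm.reindex(anchors.index), n_groups)
    rows = []
    for g in range(groups.max() + 1):
        members = anchors.loc[groups[groups == g].index]
        if members.empty:
            rows.append(np.zeros(config.n_bins))
            continue
        rows.append(
            tss_profile(reads, members, config, library_size, smooth=smooth)
            / len(members)
        )
    return pd.DataFrame(rows)


def size_normalized_profile(
    reads: pd.DataFrame,
    regions: pd.DataFrame,
    config: ProfileConfig,
    library_size: int,
) -> np.ndarray:
    """Average profile over regions rescaled onto ``n_region_bins`` bins.

    Each region is divided into equal bins; shifted read positions are
    counted per bin and normalized by bin length (bp), region count, and
    library size (per 1e7 reads).  Regions shorter than the bin count are
    skipped with a log notice.
    """
    if regions.empty:
        raise ValueError("size-normalized profile needs >= 1 region")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    nb = config.n_region_bins
    profile = np.zeros(nb)
    n_used = 0
    pos = shifted_positions(reads, config.shift) if not reads.empty else np.array([])
    chroms = reads["chrom"].to_numpy() if not reads.empty else np.array([])
    by_chrom = {c: np.sort(pos[chroms == c]) for c in np.unique(chroms)}
    for r in regions.itertuples():
        length = r.end - r.start
        if length < nb:
            logger.info(
                "region %s:%d-%d shorter than %d bins: skipped",
                r.chrom, r.start, r.end, nb,
            )
            continue
        n_used += 1
        p = by_chrom.get(r.chrom)
        if p is None:
            continue
        lo = np.searchsorted(p, r.start, side="left")
        hi = np.searchsorted(p, r.end, side="left")
        if hi == lo:
            continue
        edges = np.linspace(r.start, r.end, nb + 1)
        counts, _ = np.histogram(p[lo:hi], bins=edges)
        bin_lengths = np.diff(edges)
        profile += counts / bin_lengths
    if n_used == 0:
        raise ValueError("all regions were shorter than the bin count")
    return profile / n_used / (library_size / 1e7)
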