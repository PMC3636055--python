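"""Broad-domain island calling from window counts, with edge nibbling.

The caller follows the SICER scheme: the genome is tiled with fixed-size
windows, a window is *eligible* when its strand-shifted read count reaches
a Poisson-tail threshold over the genomic background, and maximal runs of
eligible windows separated by at most ``gap_windows`` ineligible windows
are joined into islands.  Island significance is assessed against a
matched input-control library with a scaled Poisson test and
Benjamini-Hochberg correction.  Because windows can be large relative to
the underlying enriched region, island edges are then "nibbled": the
outermost windows are trimmed at the cut that maximizes the read-density
contrast between the retained and removed portions.

Run at small window / zero gap settings against a control, the same
caller doubles as the point-source peak producer used for the RNA PolII
gene-binding rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomeSpec, GeneModel, shifted_positions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerConfig:
    """Island-caller parameters for one mark.

    ``window``: tiling window size in bp.  ``gap_windows``: number of
    consecutive ineligible windows an island may bridge.  ``fragment_size``:
    sequenced fragment length; reads are shifted by half of it toward the
    fragment center.  ``fdr``: island-level Benjamini-Hochberg threshold.
    ``eligibility_p``: per-window Poisson upper-tail threshold defining
    window eligibility (SICER's published default 0.20).
    ``e_value``: candidate-count cutoff used only when no control library
    is available.
    """

    window: int = 200
    gap_windows: int = 1
    fragment_size: int = 150
    fdr: float = 1e-5
    eligibility_p: float = 0.20
    e_value: float = 100.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.gap_windows < 0:
            raise ValueError("gap_windows must be >= 0")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if not (0 < self.eligibility_p < 1):
            raise ValueError("eligibility_p must be in (0, 1)")


#: Per-mark defaults.  Window 200 throughout; gaps per mark (in windows).
#: The broad marks H3K27me1/H3K27me3 use gap 3 (600 bp), the classic
#: broad-domain setting for a 200 bp window.
DEFAULT_MARK_CONFIGS: dict[str, CallerConfig] = {
    "BRG1": CallerConfig(window=200, gap_windows=3),
    "H2A.Z": CallerConfig(window=200, gap_windows=2),
    "H3K4me1": CallerConfig(window=200, gap_windows=1),
    "H3K4me3": CallerConfig(window=200, gap_windows=1),
    "H3K27me1": CallerConfig(window=200, gap_windows=3),
    "H3K27me3": CallerConfig(window=200, gap_windows=3),
    "PolII": CallerConfig(window=200, gap_windows=0),
}


@dataclass(frozen=True)
class WindowCounts:
    """Shifted-read counts in non-overlapping windows tiling each chromosome."""

    window: int
    counts: Mapping[str, np.ndarray]
    total_reads: int

    def island_count(self, chrom: str, start: int, end: int) -> int:
        """Total window-count mass over windows intersecting [start, end)."""
        arr = self.counts.get(chrom)
        if arr is None:
            return 0
        first = start // self.window
        last = (end - 1) // self.window
        return int(arr[first : last + 1].sum())


@dataclass(frozen=True)
class Island:
    """A contiguous enriched domain for one mark in one cell type."""

    chrom: str
    start: int
    end: int
    read_count: int
    score: float
    p_value: float | None = None
    q_value: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def islands_to_frame(islands: Sequence[Island]) -> pd.DataFrame:
    """Islands as a chrom/start/end DataFrame (plus score columns)."""
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start": np.asarray([i.start for i in islands], dtype=np.int64),
            "end": np.asarray([i.end for i in islands], dtype=np.int64),
            "read_count": [i.read_count for i in islands],
            "score": [i.score for i in islands],
            "q_value": [i.q_value for i in islands],
        }
    )


def write_islands_bed(islands: Sequence[Island], path) -> None:
    """BED6: score column = island score x10 rounded, name = ``q=<value>``."""
    with open(path, "w") as fh:
        for isl in islands:
            q = "NA" if isl.q_value is None else f"{isl.q_value:.3g}"
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tq={q}"
                f"\t{round(isl.score * 10)}\t.\n"
            )


def count_windows(
    reads: pd.DataFrame, config: CallerConfig, genome: GenomeSpec
) -> WindowCounts:
    """Bin strand-shifted read positions into tiling windows.

    Each read contributes one count to the window containing its position
    shifted by ``fragment_size / 2`` toward the fragment center.
    """
    w = config.window
    counts: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        counts[chrom] = np.zeros(-(-length // w), dtype=np.int64)
    total = 0
    if not reads.empty:
        pos = shifted_positions(reads, config.fragment_size // 2)
        chroms = reads["chrom"].to_numpy()
        for chrom in np.unique(chroms):
            if chrom not in counts:
                continue
            p = pos[chroms == chrom]
            length = genome.chrom_lengths[chrom]
            p = np.minimum(p, length - 1)  # clamp off-end shifts
            binned = np.bincount(p // w, minlength=len(counts[chrom]))
            counts[chrom] += binned.astype(np.int64)
            total += len(p)
    return WindowCounts(window=w, counts=counts, total_reads=total)


def background_rate(
    total_reads: int, config: CallerConfig, genome: GenomeSpec
) -> float:
    """Expected background reads per window over the mappable genome."""
    return (
        total_reads * config.window / (genome.effective_fraction * genome.total_length)
    )


def eligibility_threshold(bg_rate: float, eligibility_p: float) -> int:
    """Smallest integer k >= 1 with P(X >= k | Poisson(bg_rate)) < p."""
    if bg_rate <= 0:
        raise ValueError("background rate must be > 0")
    k = 1
    while stats.poisson.sf(k - 1, bg_rate) >= eligibility_p:
        k += 1
    return k


def _window_score(count: int, bg_rate: float) -> float:
    """-ln Poisson upper tail of a window count; capped for underflow."""
    p = stats.poisson.sf(count - 1, bg_rate)
    if p <= 0:
        # fall back to a Stirling-based log tail bound for extreme counts
        return float(count * math.log(count / bg_rate) - count + bg_rate)
    return float(-math.log(p))


def call_islands(
    window_counts: WindowCounts,
    config: CallerConfig,
    genome: GenomeSpec,
    bg_rate: float | None = None,
) -> list[Island]:
    """Join runs of eligible windows (bridging small gaps) into islands.

    An island's score is the sum over its eligible windows of
    ``-ln P(X >= count | Poisson(background))``; its read count covers all
    windows in its span, gap windows included.
    """
    if bg_rate is None:
        bg_rate = background_rate(window_counts.total_reads, config, genome)
    if bg_rate <= 0:
        return []
    threshold = eligibility_threshold(bg_rate, config.eligibility_p)
    w = config.window
    islands: list[Island] = []
    score_cache: dict[int, float] = {}
    for chrom in sorted(window_counts.counts):
        arr = window_counts.counts[chrom]
        eligible = np.flatnonzero(arr >= threshold)
        if eligible.size == 0:
            continue
        chrom_len = genome.chrom_lengths[chrom]
        run_start = eligible[0]
        prev = eligible[0]
        runs: list[tuple[int, int]] = []
        for idx in eligible[1:]:
            if idx - prev - 1 > config.gap_windows:
                runs.append((run_start, prev))
                run_start = idx
            prev = idx
        runs.append((run_start, prev))
        for first, last in runs:
            span = arr[first : last + 1]
            score = 0.0
            for c in span[span >= threshold]:
                c = int(c)
                if c not in score_cache:
                    score_cache[c] = _window_score(c, bg_rate)
                score += score_cache[c]
            islands.append(
                Island(
                    chrom=chrom,
                    start=int(first * w),
                    end=int(min((last + 1) * w, chrom_len)),
                    read_count=int(span.sum()),
                    score=score,
                )
            )
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def assess_significance(
    islands: Sequence[Island],
    chip_counts: WindowCounts,
    control_counts: WindowCounts | None,
    config: CallerConfig,
    genome: GenomeSpec | None = None,
) -> list[Island]:
    """Attach p/q values and filter islands at the configured FDR.

    With a control library: per island, the ChIP count is tested against a
    Poisson expectation of ``max(control count, 1)`` scaled by the library
    size ratio, floored at the genome-wide background expectation for the
    island's span (a local/global-lambda floor; without it, islands whose
    control count is 0-1 by chance are tested against an unrealistically
    small expectation).  q values are Benjamini-Hochberg over all
    candidates.  Without a control, an E-value filter against the genomic
    background is used instead (expected number of equal-or-better
    islands).
    """
    if not islands:
        return []
    for isl in islands:
        if isl.read_count < 1:
            raise ValueError("island with zero reads cannot be assessed")
    if control_counts is None or control_counts.total_reads == 0:
        if genome is None:
            raise ValueError("genome required for control-free E-value mode")
        logger.warning("no control library: falling back to E-value mode")
        bg = background_rate(chip_counts.total_reads, config, genome)
        pvals = np.array(
            [
                stats.poisson.sf(
                    isl.read_count - 1, bg * isl.length / config.window
                )
                for isl in islands
            ]
        )
        evals = pvals * len(islands)
        kept = [
            replace(isl, p_value=float(p))
            for isl, p, e in zip(islands, pvals, evals)
            if e <= config.e_value
        ]
        return kept
    ratio = chip_counts.total_reads / control_counts.total_reads
    bg = (
        background_rate(chip_counts.total_reads, config, genome)
        if genome is not None
        else 0.0
    )
    pvals = np.empty(len(islands))
    for i, isl in enumerate(islands):
        ctrl = control_counts.island_count(isl.chrom, isl.start, isl.end)
        expected = max(
            max(ctrl, 1) * ratio, bg * isl.length / config.window
        )
        pvals[i] = stats.poisson.sf(isl.read_count - 1, expected)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        replace(isl, p_value=float(p), q_value=float(q))
        for isl, p, q in zip(islands, pvals, qvals)
        if q <= config.fdr
    ]
    return out


def _density(n_reads: int, length: int) -> float:
    return n_reads / length if length > 0 else 0.0


def _count_in(pos_sorted: np.ndarray, start: int, end: int) -> int:
    return int(
        np.searchsorted(pos_sorted, end, side="left")
        - np.searchsorted(pos_sorted, start, side="left")
    )


def nibble_island(
    island: Island,
    shifted_pos: np.ndarray,
    config: CallerConfig,
    bg_rate: float | None = None,
    step: int = 10,
) -> Island:
    """Trim island edges to maximize retained-vs-removed density contrast.

    For each end independently, candidate cut points are scanned at
    ``step`` bp intervals strictly inside the outermost window; the cut
    maximizing density(retained part) - density(removed part) is applied
    when that difference is positive and the removed part is sparser than
    the island-wide mean density.  The scan repeats on the shrinking edge
    segment until no admissible cut remains, which makes the operation
    idempotent.  ``shifted_pos`` holds the strand-shifted read positions
    for the island's chromosome (need not be pre-sorted).
    """
    w = config.window
    pos = np.sort(shifted_pos)
    start, end = island.start, island.end

    def mean_density() -> float:
        return _density(_count_in(pos, start, end), end - start)

    # Alternate left/right scans until neither end moves.  The admissibility
    # gate depends on the island-wide mean density, which each trim changes,
    # so only the joint fixed point is idempotent.
    changed = True
    while changed:
        changed = False
        # left edge
        seg_end = min((start // w + 1) * w, end)
        best_cut, best_diff = None, 0.0
        for cut in range(start + step, seg_end, step):
            removed = _density(_count_in(pos, start, cut), cut - start)
            retained = _density(_count_in(pos, cut, seg_end), seg_end - cut)
            diff = retained - removed
            if diff > best_diff and removed < mean_density():
                best_cut, best_diff = cut, diff
        if best_cut is not None:
            start = best_cut
            changed = True
        # right edge (mirrored)
        seg_start = max(((end - 1) // w) * w, start)
        best_cut, best_diff = None, 0.0
        for cut in range(end - step, seg_start, -step):
            removed = _density(_count_in(pos, cut, end), end - cut)
            retained = _density(_count_in(pos, seg_start, cut), cut - seg_start)
            diff = retained - removed
            if diff > best_diff and removed < mean_density():
                best_cut, best_diff = cut, diff
        if best_cut is not None:
            end = best_cut
            changed = True

    if (start, end) == (island.start, island.end):
        return island
    n = _count_in(pos, start, end)
    if bg_rate is not None and bg_rate > 0:
        score = _window_score(max(n, 1), bg_rate * (end - start) / w)
    else:
        score = island.score
    return replace(island, start=start, end=end, read_count=n, score=score)


def nibble_islands(
    islands: Sequence[Island],
    reads: pd.DataFrame,
    config: CallerConfig,
    bg_rate: float | None = None,
) -> list[Island]:
    """Nibble every island using the full read set (grouped by chromosome)."""
    if not islands:
        return []
    pos = shifted_positions(reads, config.fragment_size // 2)
    chroms = reads["chrom"].to_numpy()
    by_chrom = {c: np.sort(pos[chroms == c]) for c in np.unique(chroms)}
    empty = np.array([], dtype=np.int64)
    return [
        nibble_island(isl, by_chrom.get(isl.chrom, empty), config, bg_rate)
        for isl in islands
    ]


def call_and_filter(
    reads: pd.DataFrame,
    control_reads: pd.DataFrame | None,
    config: CallerConfig,
    genome: GenomeSpec,
    nibble: bool = True,
) -> list[Island]:
    """Full per-library pipeline: count, call, filter at FDR, then nibble.

    Nibbling runs after significance filtering, so trimmed coordinates
    never change which islands survive.
    """
    counts = count_windows(reads, config, genome)
    bg = background_rate(counts.total_reads, config, genome)
    candidates = call_islands(counts, config, genome, bg)
    ctrl_counts = (
        count_windows(control_reads, config, genome)
        if control_reads is not None and not control_reads.empty
        else None
    )
    kept = assess_significance(candidates, counts, ctrl_counts, config, genome)
    if nibble:
        kept = nibble_islands(kept, reads, config, bg)
    return kept


def polII_gene_binding(
    gene: GeneModel, peaks: pd.DataFrame
) -> bool:
    """True iff a peak overlaps TSS-5kb .. TES+3kb (strand-relative)."""
    if gene.strand == "+":
        lo = gene.interval.start - 5000
        hi = gene.interval.end + 3000
    else:
        lo = gene.interval.start - 3000
        hi = gene.interval.end + 5000
    sub = peaks[peaks["chrom"] == gene.interval.chrom]
    if sub.empty:
        return False
    return bool(
        ((sub["start"].to_numpy() < hi) & (sub["end"].to_numpy() > lo)).any()
    )
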