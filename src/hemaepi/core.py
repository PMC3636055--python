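"""Coordinate conventions, interval arithmetic, and readers/writers.

All coordinates are 0-based half-open ``[start, end)`` (BED-native)
throughout the package.  The TSS of a minus-strand gene is ``end - 1``.
Collections of reads and intervals are held as pandas DataFrames with
columns ``chrom, start, end`` (plus ``strand`` for reads); single records
are small frozen dataclasses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand"]
INTERVAL_COLUMNS = ["chrom", "start", "end"]


class BedParseError(ValueError):
    """A BED-family file could not be parsed; the message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Read:
    """A mapped sequencing read: an interval plus a strand."""

    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: TSS-to-TES span, strand, and exon structure."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = self.interval.start - 1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if ex.start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted, disjoint")
            prev_end = ex.end
        if self.exon_length < 1:
            raise ValueError(f"{self.gene_id}: summed exon length must be >= 1")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware base position)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware base position)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def exon_length(self) -> int:
        return sum(ex.length for ex in self.exons)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths plus the uniquely-mappable fraction of the genome.

    ``effective_fraction`` defaults to 0.68, the uniquely mappable share of
    a human assembly for 25 bp reads; synthetic genomes with no mappability
    structure should use 1.0.
    """

    chrom_lengths: Mapping[str, int]
    effective_fraction: float = 0.68

    def __post_init__(self) -> None:
        if not all(v > 0 for v in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if not (0 < self.effective_fraction <= 1):
            raise ValueError("effective_fraction must be in (0, 1]")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _validate_read_frame(df: pd.DataFrame, path: str | Path) -> None:
    bad = df["start"] >= df["end"]
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise BedParseError(f"{path}: start >= end at line {line}")
    if (df["start"] < 0).any():
        line = int(np.flatnonzero((df["start"] < 0).to_numpy())[0]) + 1
        raise BedParseError(f"{path}: negative start at line {line}")


def read_bed_reads(path: str | Path, drop_chrY: bool = True) -> pd.DataFrame:
    """Read mapped reads from a BED3/BED6 file.

    BED3 lines get strand ``+``.  Reads on the Y chromosome are dropped by
    default (some subjects in mixed-donor designs are female, so Y reads
    are uninterpretable).
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            dtype={0: str}, engine="c",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=READ_COLUMNS).astype(
            {"start": np.int64, "end": np.int64}
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise BedParseError(f"{path}: {exc}") from exc
    if raw.shape[1] == 3:
        df = raw.iloc[:, :3].copy()
        df.columns = INTERVAL_COLUMNS
        df["strand"] = "+"
    elif raw.shape[1] >= 6:
        df = raw.iloc[:, [0, 1, 2, 5]].copy()
        df.columns = READ_COLUMNS
    else:
        raise BedParseError(
            f"{path}: expected 3 or >=6 tab-separated fields, got {raw.shape[1]}"
        )
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise BedParseError(f"{path}: non-integer coordinates ({exc})") from exc
    _validate_read_frame(df, path)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise BedParseError(f"{path}: invalid strand at line {line}")
    if drop_chrY:
        df = df[~df["chrom"].isin(["chrY", "Y"])]
    return df.reset_index(drop=True)


def write_bed_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads as BED6 (name '.', score 0); lossless round trip."""
    out = reads.loc[:, INTERVAL_COLUMNS].copy()
    out["name"] = "."
    out["score"] = 0
    out["strand"] = reads["strand"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read plain intervals (first three BED columns) from a BED file."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=INTERVAL_COLUMNS).astype(
            {"start": np.int64, "end": np.int64}
        )
    if raw.shape[1] < 3:
        raise BedParseError(f"{path}: expected >=3 tab-separated fields")
    df = raw.iloc[:, :3].copy()
    df.columns = INTERVAL_COLUMNS
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _validate_read_frame(df, path)
    return df.reset_index(drop=True)


def write_bed_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.loc[:, INTERVAL_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise BedParseError(f"{path}: expected two columns at line {i}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_annotation(path: str | Path, drop_chrY: bool = True) -> list[GeneModel]:
    """Read gene models from a BED12 file.

    Columns used: chrom, start, end, name, strand, blockCount, blockSizes,
    blockStarts.  Blocks become exons.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise BedParseError(f"{path}: expected 12 BED fields at line {i}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            if drop_chrY and chrom in ("chrY", "Y"):
                continue
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + sz)
                for off, sz in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start, end), strand, exons)
            )
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.interval.start, g.interval.end
            sizes = ",".join(str(ex.length) for ex in g.exons)
            offsets = ",".join(str(ex.start - start) for ex in g.exons)
            fh.write(
                f"{g.interval.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{start}\t{end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Read and interval arithmetic
# ---------------------------------------------------------------------------


def deduplicate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one read per (chrom, 5' position, strand).

    The 5' position is ``start`` for plus-strand reads and ``end - 1`` for
    minus-strand reads, so reads of different length at the same sequencing
    position count as duplicates.  Idempotent and order-independent.
    """
    if reads.empty:
        return reads.reset_index(drop=True)
    pos = np.where(
        reads["strand"].to_numpy() == "+",
        reads["start"].to_numpy(),
        reads["end"].to_numpy() - 1,
    )
    key = pd.DataFrame({"chrom": reads["chrom"], "pos": pos, "strand": reads["strand"]})
    keep = ~key.duplicated()
    out = reads[keep].sort_values(READ_COLUMNS, kind="stable")
    return out.reset_index(drop=True)


def shift_read_position(read: Read, shift: int) -> int:
    """Strand-aware shifted position: a fragment-center proxy for one read."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if read.strand == "+":
        pos = read.interval.start + shift
    else:
        pos = read.interval.end - 1 - shift
    if pos < 0:
        logger.warning("shifted position %d clamped to 0", pos)
        pos = 0
    return pos


def shifted_positions(reads: pd.DataFrame, shift: int) -> np.ndarray:
    """Vectorized strand-aware shift; off-chromosome positions clamp to 0."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    pos = np.where(
        reads["strand"].to_numpy() == "+",
        reads["start"].to_numpy() + shift,
        reads["end"].to_numpy() - 1 - shift,
    )
    n_clamped = int((pos < 0).sum())
    if n_clamped:
        logger.warning("%d shifted positions clamped to chromosome start", n_clamped)
    return np.maximum(pos, 0)


def merge_intervals(intervals: pd.DataFrame | Iterable[GenomicInterval]) -> pd.DataFrame:
    """Minimal disjoint sorted cover of the union; touching intervals merge."""
    if not isinstance(intervals, pd.DataFrame):
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        intervals = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    if intervals.empty:
        return pd.DataFrame(columns=INTERVAL_COLUMNS).astype(
            {"start": np.int64, "end": np.int64}
        )
    df = intervals.sort_values(["chrom", "start", "end"], kind="stable")
    out_rows: list[tuple[str, int, int]] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        running_max = np.maximum.accumulate(ends)
        # a new block starts where the interval begins beyond all prior ends
        new_block = np.ones(len(sub), dtype=bool)
        new_block[1:] = starts[1:] > running_max[:-1]
        block_id = np.cumsum(new_block) - 1
        for b in range(block_id[-1] + 1):
            mask = block_id == b
            out_rows.append((chrom, int(starts[mask][0]), int(ends[mask].max())))
    out = pd.DataFrame(out_rows, columns=INTERVAL_COLUMNS)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def total_length(intervals: pd.DataFrame) -> int:
    if intervals.empty:
        return 0
    return int((intervals["end"] - intervals["start"]).sum())


def write_track(
    reads: pd.DataFrame,
    window: int,
    shift: int,
    library_size: int,
    path: str | Path,
    genome: GenomeSpec | None = None,
) -> None:
    """Write a bedGraph coverage track from strand-shifted read positions.

    Per non-overlapping window, value = shifted-read count x 1e7 /
    ``library_size``; zero windows are omitted.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    scale = 1e7 / library_size
    with open(path, "w") as fh:
        if reads.empty:
            return
        pos = shifted_positions(reads, shift)
        df = pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "win": pos // window})
        counts = df.groupby(["chrom", "win"]).size()
        for (chrom, win), n in counts.items():
            start = int(win) * window
            end = start + window
            if genome is not None and chrom in genome.chrom_lengths:
                end = min(end, genome.chrom_lengths[chrom])
            fh.write(f"{chrom}\t{start}\t{end}\t{n * scale:.6g}\n")


def overlaps_any(
    query: pd.DataFrame, targets: pd.DataFrame
) -> np.ndarray:
    """Boolean per query row: does it overlap any target interval?

    Targets are merged internally; both frames use chrom/start/end columns.
    """
    result = np.zeros(len(query), dtype=bool)
    if query.empty or targets.empty:
        return result
    merged = merge_intervals(targets)
    for chrom, sub in merged.groupby("chrom"):
        qmask = (query["chrom"] == chrom).to_numpy()
        if not qmask.any():
            continue
        t_starts = sub["start"].to_numpy()
        t_ends = sub["end"].to_numpy()
        q_starts = query.loc[qmask, "start"].to_numpy()
        q_ends = query.loc[qmask, "end"].to_numpy()
        # overlap iff some target with t_start < q_end and t_end > q_start
        idx = np.searchsorted(t_starts, q_ends, side="left") - 1
        ok = idx >= 0
        ok[ok] &= t_ends[idx[ok]] > q_starts[ok]
        result[np.flatnonzero(qmask)] = ok
    return result


def positions_in_intervals(
    chroms: np.ndarray, positions: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean per position: does it fall inside any (merged) interval?"""
    result = np.zeros(len(positions), dtype=bool)
    if len(positions) == 0 or intervals.empty:
        return result
    merged = merge_intervals(intervals)
    for chrom, sub in merged.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        result[np.flatnonzero(mask)] = ok
    return result
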