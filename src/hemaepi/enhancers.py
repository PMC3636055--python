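"""Enhancer prediction from H2A.Z / H3K4me1 islands and expression tests.

Potential enhancers in one cell type are the union of H2A.Z- and
H3K4me1-enriched islands lying outside every promoter zone (TSS +/- 500
bp).  Candidates from all cell types are unified into a catalog; a
region present in every type is a core potential enhancer (CPE), one
present in exactly one type is a cell-specific potential enhancer
(CSPE), anything else is a shared subset.  Regions are associated to the
nearest gene whose strand-relative flanking windows they overlap, and
the association is tested against expression with two-sample
Kolmogorov-Smirnov comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, merge_intervals, overlaps_any

logger = logging.getLogger(__name__)


def _tss_exclusion_zones(
    genes: Sequence[GeneModel], flank: int
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [g.interval.chrom for g in genes],
            "start": np.asarray([max(0, g.tss - flank) for g in genes], np.int64),
            "end": np.asarray([g.tss + flank + 1 for g in genes], np.int64),
        }
    )


def predict_enhancers(
    h2az_islands: pd.DataFrame,
    k4me1_islands: pd.DataFrame,
    genes: Sequence[GeneModel],
    exclusion_flank: int = 500,
) -> pd.DataFrame:
    """Candidate enhancers for one cell type.

    Union of the two island sets, merged, with every region overlapping a
    TSS +/- ``exclusion_flank`` zone removed.  Columns ``has_H2A.Z`` /
    ``has_H3K4me1`` record which defining marks each region carries.
    """
    pieces = [df for df in (h2az_islands, k4me1_islands) if not df.empty]
    if not pieces:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "has_H2A.Z", "has_H3K4me1"]
        )
    merged = merge_intervals(pd.concat(pieces, ignore_index=True))
    if genes:
        zones = _tss_exclusion_zones(genes, exclusion_flank)
        merged = merged[~overlaps_any(merged, zones)].reset_index(drop=True)
    merged["has_H2A.Z"] = overlaps_any(merged, h2az_islands)
    merged["has_H3K4me1"] = overlaps_any(merged, k4me1_islands)
    return merged


def flag_bivalent_enhancers(
    candidates: pd.DataFrame, k27_islands: pd.DataFrame
) -> pd.DataFrame:
    """Mark candidates carrying any H3K27me3 enrichment in their locus."""
    out = candidates.copy()
    out["bivalent"] = overlaps_any(candidates, k27_islands)
    return out


def build_catalog(candidates_by_type: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Unify per-type candidates into a cross-cell-type catalog.

    A unified region is present in a cell type when >= 1 bp of it overlaps
    a candidate from that type.  Classes: ``CPE`` (all types), ``CSPE``
    (exactly one; ``cspe_type`` names it), ``shared_subset`` otherwise.
    """
    types = list(candidates_by_type)
    if len(types) < 2:
        raise ValueError("catalog needs candidates from >= 2 cell types")
    nonempty = [df for df in candidates_by_type.values() if not df.empty]
    if not nonempty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "class", "cspe_type"]
            + [f"present_{t}" for t in types]
        )
    unified = merge_intervals(pd.concat(nonempty, ignore_index=True))
    presence = {}
    for t in types:
        presence[f"present_{t}"] = overlaps_any(unified, candidates_by_type[t])
    out = unified.assign(**presence)
    pres = out[[f"present_{t}" for t in types]].to_numpy()
    n_present = pres.sum(axis=1)
    cls = np.where(
        n_present == len(types), "CPE",
        np.where(n_present == 1, "CSPE", "shared_subset"),
    )
    cspe_type = np.where(
        n_present == 1,
        np.asarray(types, dtype=object)[pres.argmax(axis=1)],
        None,
    )
    out["class"] = cls
    out["cspe_type"] = cspe_type
    return out


def _assoc_windows(g: GeneModel, flank: int, promoter_margin: int):
    """Strand-relative (upstream, downstream) association windows."""
    if g.strand == "+":
        up = (g.tss - flank, g.tss - promoter_margin + 1)
        down = (g.tes, g.tes + flank + 1)
    else:
        up = (g.tss + promoter_margin, g.tss + flank + 1)
        down = (g.tes - flank, g.tes + 1)
    return up, down


def associate_to_gene(
    region: tuple[str, int, int],
    genes: Sequence[GeneModel],
    flank: int = 20000,
    promoter_margin: int = 500,
) -> str | None:
    """Nearest gene whose flanking window overlaps the region.

    Candidate genes are those whose strand-relative window
    [TSS-flank, TSS-promoter_margin] or [TES, TES+flank] overlaps the
    region; among candidates, the one minimizing distance from the region
    midpoint to the nearer of its TSS/TES wins, ties going to the
    lexicographically smaller gene id.
    """
    chrom, start, end = region
    mid = (start + end) // 2
    best: tuple[int, str] | None = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        up, down = _assoc_windows(g, flank, promoter_margin)
        hit = (start < up[1] and end > up[0]) or (start < down[1] and end > down[0])
        if not hit:
            continue
        dist = min(abs(mid - g.tss), abs(mid - g.tes))
        key = (dist, g.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def associate_catalog(
    catalog: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 20000,
    promoter_margin: int = 500,
) -> pd.DataFrame:
    """Attach an ``assoc_gene`` column (None when no gene qualifies)."""
    out = catalog.copy()
    out["assoc_gene"] = [
        associate_to_gene((row.chrom, row.start, row.end), genes, flank, promoter_margin)
        for row in catalog.itertuples()
    ]
    return out


@dataclass(frozen=True)
class KSComparison:
    """Two count/value distributions plus their two-sided KS test."""

    values_a: np.ndarray
    values_b: np.ndarray
    statistic: float
    p_value: float


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov statistic and p value."""
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def cspe_count_comparison(
    catalog: pd.DataFrame,
    ts_genes: set[str],
    expressed_genes: set[str],
    cell_type: str,
) -> KSComparison:
    """Per-gene CSPE counts for type-specific vs all expressed genes.

    Counts CSPEs of ``cell_type`` associated with each gene in either
    set (genes without any associated CSPE count zero), then compares the
    two count distributions with a two-sided KS test.
    """
    if not ts_genes or not expressed_genes:
        raise ValueError("gene sets must be non-empty")
    sub = catalog[
        (catalog["class"] == "CSPE") & (catalog["cspe_type"] == cell_type)
    ]
    per_gene = sub["assoc_gene"].value_counts()
    a = np.array([per_gene.get(g, 0) for g in sorted(ts_genes)], dtype=float)
    b = np.array([per_gene.get(g, 0) for g in sorted(expressed_genes)], dtype=float)
    stat, p = ks_two_sample(a, b)
    return KSComparison(values_a=a, values_b=b, statistic=stat, p_value=p)


def expression_by_enhancer_class(
    catalog: pd.DataFrame,
    rpkm: pd.Series,
    filters: Mapping[str, np.ndarray],
    trim_top: float = 0.05,
) -> dict[str, KSComparison | None]:
    """RPKM distributions of genes associated with filtered region sets.

    ``filters`` maps a label to a boolean mask over catalog rows (e.g.
    CSPEs of one type, PolII-bound CSPEs).  The global top ``trim_top``
    fraction of RPKM values is removed before any comparison; each
    filter's gene distribution is KS-tested against the trimmed all-genes
    distribution.  Filters matching nothing yield None with a log notice.
    """
    values = rpkm.sort_values()
    n_trim = int(np.floor(trim_top * len(values)))
    trimmed = values.iloc[: len(values) - n_trim] if n_trim else values
    all_vals = trimmed.to_numpy(dtype=float)
    results: dict[str, KSComparison | None] = {}
    for label, mask in filters.items():
        genes = catalog.loc[np.asarray(mask, bool), "assoc_gene"].dropna().unique()
        genes = [g for g in genes if g in trimmed.index]
        if not genes:
            logger.info("filter %r matched no regions with associated genes", label)
            results[label] = None
            continue
        vals = trimmed.loc[genes].to_numpy(dtype=float)
        stat, p = ks_two_sample(vals, all_vals)
        results[label] = KSComparison(
            values_a=vals, values_b=all_vals, statistic=stat, p_value=p
        )
    return results
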