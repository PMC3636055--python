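"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pandas as pd
import pytest

from hemaepi.core import GenomeSpec, GenomicInterval, GeneModel
from hemaepi.simulate import SimulationConfig, simulate_all


def make_gene(
    gene_id: str,
    chrom: str = "chr1",
    start: int = 10_000,
    end: int = 20_000,
    strand: str = "+",
    exons=None,
) -> GeneModel:
    if exons is None:
        exons = ((start, start + 1000), (end - 1000, end))
    return GeneModel(
        gene_id,
        GenomicInterval(chrom, start, end),
        strand,
        tuple(GenomicInterval(chrom, a, b) for a, b in exons),
    )


def reads_frame(rows) -> pd.DataFrame:
    """rows: iterable of (chrom, start, end, strand)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def intervals_frame(rows) -> pd.DataFrame:
    """rows: iterable of (chrom, start, end)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if df.empty:
        return df.astype({"start": np.int64, "end": np.int64}, errors="ignore")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec(chrom_lengths={"chr1": 100_000}, effective_fraction=1.0)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced full simulation shared by read-level tests."""
    config = SimulationConfig(
        seed=11,
        n_chroms=1,
        chrom_length=2_000_000,
        n_genes=60,
        n_distal_k27_domains=15,
        n_cpe=10,
        n_cspe_per_type=6,
        ts_genes_per_type=4,
        marks=("H3K4me3", "H3K27me3", "H2A.Z", "H3K4me1"),
    )
    return simulate_all(config)
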