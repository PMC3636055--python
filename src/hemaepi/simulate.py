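"""Synthetic multi-cell-type epigenome with planted ground truth.

The generator emulates the inputs of a hematopoietic epigenome
comparison at desk scale: a toy genome, gene models, CpG islands,
per-mark/per-cell-type ChIP read files (Poisson background plus planted
enriched domains), planted promoter chromatin states evolving along a
lineage tree, planted core and cell-specific enhancers, and a
negative-binomial expression table with planted type-specific genes.
Every planted feature is recorded in a :class:`TruthManifest` so each
pipeline stage can be scored against known truth.

All randomness flows from one seed through ``numpy``'s SeedSequence
spawning, so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    read_bed_intervals,
    read_bed_reads,
    read_chrom_sizes,
    read_gene_annotation,
    write_bed_intervals,
    write_bed_reads,
    write_chrom_sizes,
    write_gene_annotation,
)
from .promoters import LineageTree, STATES

CHIP_MARKS = (
    "H3K4me1", "H3K4me3", "H3K27me1", "H3K27me3", "H2A.Z", "BRG1", "PolII",
)


def _stream_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Platform-stable per-stream seed derived from the master seed."""
    return np.random.SeedSequence([seed, zlib.crc32(label.encode())])


def _default_fold() -> dict[str, float]:
    # Point-source marks (promoter-proximal) show stronger local enrichment
    # than broad domains in real ChIP data; folds reflect that.
    return {
        "H3K4me3": 12.0,
        "H2A.Z": 8.0,
        "H3K4me1": 8.0,
        "BRG1": 8.0,
        "PolII": 10.0,
        "H3K27me3": 5.0,
        "H3K27me1": 5.0,
    }


def _default_root_probs() -> dict[str, float]:
    return {"bivalent": 0.30, "K4_only": 0.35, "K27_only": 0.10, "none": 0.25}


def _default_transitions() -> dict[str, dict[str, float]]:
    # Rows sum to 1.  Bivalency both resolves (all three fates) and is
    # newly established from every origin, so each lineage edge exercises
    # every resolution and establishment category.
    return {
        "bivalent": {"bivalent": 0.35, "K4_only": 0.30, "K27_only": 0.25, "none": 0.10},
        "K4_only": {"bivalent": 0.06, "K4_only": 0.80, "K27_only": 0.04, "none": 0.10},
        "K27_only": {"bivalent": 0.08, "K4_only": 0.05, "K27_only": 0.70, "none": 0.17},
        "none": {"bivalent": 0.04, "K4_only": 0.10, "K27_only": 0.08, "none": 0.78},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic epigenome.

    Scale defaults (2 x 5 Mb chromosomes, 300 genes, 5 cell types,
    ~50k reads per mark and type) keep a full run to minutes on one CPU
    while giving every downstream analysis enough events to score.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    cell_types: tuple[str, ...] = ("ESC", "HSPC", "pRBC", "T", "B")
    lineage_edges: tuple[tuple[str, str], ...] = (
        ("ESC", "HSPC"), ("HSPC", "pRBC"), ("HSPC", "T"), ("HSPC", "B"),
    )
    expression_types: tuple[str, ...] = ("HSPC", "pRBC", "T", "B")
    marks: tuple[str, ...] = CHIP_MARKS

    # read model
    background_rate: float = 5e-3      # reads per bp per mark/type
    read_length: int = 25
    fragment_size: int = 150
    enrichment_fold: dict[str, float] = field(default_factory=_default_fold)

    # planted domain geometry (bp ranges)
    k4_domain_length: tuple[int, int] = (1000, 2000)
    k27_promoter_domain_length: tuple[int, int] = (4000, 8000)
    k27_distal_domain_length: tuple[int, int] = (4000, 20000)
    n_distal_k27_domains: int = 60

    # promoter state process
    root_state_probs: dict[str, float] = field(default_factory=_default_root_probs)
    transition_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_transitions
    )

    # CpG model: probability of a promoter CpG island given consistent /
    # inconsistent H3K4me3 marking across the four blood cell types
    p_cpg_consistent: float = 0.9
    p_cpg_other: float = 0.3

    # enhancers
    n_cpe: int = 40
    n_cspe_per_type: int = 20
    enhancer_length: tuple[int, int] = (1000, 2000)
    cspe_per_ts_gene: int = 2

    # expression
    ts_genes_per_type: int = 10
    ts_fold: float = 64.0             # 2**6
    dispersion: float = 0.02          # NB dispersion phi (BCV ~ 0.14)
    base_mean: float = 50.0           # lognormal median of per-gene means
    base_mean_sigma: float = 0.7
    expressed_mean_threshold: float = 8.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if abs(sum(self.root_state_probs.values()) - 1) > 1e-9:
            raise ValueError("root state probabilities must sum to 1")
        for state, row in self.transition_probs.items():
            if abs(sum(row.values()) - 1) > 1e-9:
                raise ValueError(f"transition row {state!r} must sum to 1")
            if any(p < 0 or p > 1 for p in row.values()):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def lineage(self) -> LineageTree:
        return LineageTree(edges=self.lineage_edges)


@dataclass
class TruthManifest:
    """Everything planted by the generator, for scoring recoveries."""

    config: SimulationConfig
    genome: GenomeSpec
    genes: list[GeneModel]
    cpg: pd.DataFrame
    states: pd.DataFrame            # gene x cell type, values in STATES
    domains: pd.DataFrame           # mark, cell_type, chrom, start, end, fold
    enhancers: pd.DataFrame         # chrom,start,end,class,cell_type,marks,target
    ts_genes: dict[str, list[str]]
    expression_means: pd.DataFrame  # gene x expression type
    polII_bound: pd.DataFrame       # gene x cell type (bool)

    def domains_for(self, mark: str, cell_type: str) -> pd.DataFrame:
        sub = self.domains[
            (self.domains["mark"] == mark) & (self.domains["cell_type"] == cell_type)
        ]
        return sub[["chrom", "start", "end", "fold"]].reset_index(drop=True)

    def validate(self) -> None:
        """Internal consistency: planted bivalency implies both domains."""
        for g in self.genes:
            for ct in self.states.columns:
                if self.states.loc[g.gene_id, ct] != "bivalent":
                    continue
                lo, hi = g.tss - 500, g.tss + 501
                for mark in ("H3K4me3", "H3K27me3"):
                    dom = self.domains_for(mark, ct)
                    dom = dom[dom["chrom"] == g.interval.chrom]
                    ok = ((dom["start"] < hi) & (dom["end"] > lo)).any()
                    if not ok:
                        raise AssertionError(
                            f"{g.gene_id}/{ct}: bivalent without {mark} domain"
                        )


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSpec, list[GeneModel]]:
    """Toy genome plus non-overlapping gene models on a jittered grid.

    The synthetic genome has no mappability structure, so its effective
    fraction is 1.0.  Genes are laid out in equal slots per chromosome
    with jitter, guaranteeing collision-free TSSs and wide intergenic
    space for planting distal elements.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    genome = GenomeSpec(chrom_lengths=chrom_lengths, effective_fraction=1.0)
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genome, genes
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gene_idx = 0
    for ci, (chrom, length) in enumerate(chrom_lengths.items()):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = length // n
        if slot < 24000:
            raise ValueError("genes do not fit: need >= 24 kb per gene slot")
        for k in range(n):
            center = k * slot + slot // 2 + int(rng.integers(-2000, 2001))
            gene_len = int(rng.integers(2000, 10001))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start = center
                end = center + gene_len
            else:
                start = center - gene_len + 1
                end = center + 1
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(1, gene_len), 2 * n_exons, False))
            exons = []
            for j in range(n_exons):
                a, b = start + int(cuts[2 * j]), start + int(cuts[2 * j + 1])
                exons.append(GenomicInterval(chrom, a, b))
            gene_id = f"g{gene_idx:04d}"
            gene_idx += 1
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start, end), strand,
                          tuple(exons))
            )
    return genome, genes


# ---------------------------------------------------------------------------
# Landscape planting
# ---------------------------------------------------------------------------


def _sample_state(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    states = list(probs)
    p = np.array([probs[s] for s in states])
    return states[rng.choice(len(states), p=p / p.sum())]


def plant_expression(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-gene expression means with planted type-specific genes.

    Base means are lognormal around ``base_mean``; each expression type
    gets ``ts_genes_per_type`` disjoint genes whose mean is multiplied by
    ``ts_fold`` in that type only.
    """
    gene_ids = list(gene_ids)
    base = config.base_mean * np.exp(
        rng.normal(0.0, config.base_mean_sigma, size=len(gene_ids))
    )
    means = pd.DataFrame(
        {ct: base.copy() for ct in config.expression_types}, index=gene_ids
    )
    shuffled = list(rng.permutation(gene_ids))
    ts_genes: dict[str, list[str]] = {}
    cursor = 0
    for ct in config.expression_types:
        picked = shuffled[cursor : cursor + config.ts_genes_per_type]
        cursor += config.ts_genes_per_type
        ts_genes[ct] = sorted(picked)
        means.loc[picked, ct] *= config.ts_fold
    return means, ts_genes


class _Placer:
    """Rejection-sampler for non-colliding intergenic placements."""

    def __init__(self, genome: GenomeSpec, genes: Sequence[GeneModel],
                 rng: np.random.Generator, tss_margin: int = 6000,
                 spacing: int = 2000) -> None:
        # tss_margin covers the widest promoter-proximal planted domain;
        # spacing exceeds the caller's largest gap-bridging distance, so
        # distinct planted features can never fuse into one called island.
        self.genome = genome
        self.rng = rng
        self.spacing = spacing
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in genome.chrom_lengths
        }
        for g in genes:
            self.occupied[g.interval.chrom].append(
                (g.tss - tss_margin, g.tss + tss_margin)
            )

    def _collides(self, chrom: str, start: int, end: int) -> bool:
        for a, b in self.occupied[chrom]:
            if start < b + self.spacing and end + self.spacing > a:
                return True
        return False

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place(self, length: int, chrom: str | None = None,
              lo: int | None = None, hi: int | None = None,
              max_tries: int = 200) -> tuple[str, int, int] | None:
        chroms = list(self.genome.chrom_lengths)
        for _ in range(max_tries):
            c = chrom or chroms[self.rng.integers(len(chroms))]
            clen = self.genome.chrom_lengths[c]
            a = max(0, lo) if lo is not None else 0
            b = hi if hi is not None else clen - length
            b = min(b, clen - length)
            if b <= a:
                return None
            start = int(self.rng.integers(a, b))
            if not self._collides(c, start, start + length):
                self.reserve(c, start, start + length)
                return c, start, start + length
        return None


def plant_chromatin_landscape(
    genome: GenomeSpec,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthManifest:
    """Plant promoter states, domains, enhancers, CpGs, and expression."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    lineage = config.lineage
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}

    # --- promoter states along the lineage ---------------------------------
    states = pd.DataFrame(index=gene_ids, columns=list(config.cell_types),
                          dtype=object)
    order = [lineage.root]
    while len(order) < len(lineage.nodes):
        for p, c in lineage.edges:
            if p in order and c not in order:
                order.append(c)
    for ct in order:
        parent = lineage.parent_of(ct)
        for gid in gene_ids:
            if parent is None:
                states.loc[gid, ct] = _sample_state(rng, config.root_state_probs)
            else:
                prev = states.loc[gid, parent]
                states.loc[gid, ct] = _sample_state(
                    rng, config.transition_probs[prev]
                )

    # --- expression means and TS genes -------------------------------------
    means, ts_genes = plant_expression(gene_ids, config, rng)
    expressed = means >= config.expressed_mean_threshold

    # --- PolII binding truth ------------------------------------------------
    pol_bound = pd.DataFrame(False, index=gene_ids,
                             columns=list(config.cell_types))
    for ct in config.cell_types:
        if ct in config.expression_types:
            pol_bound[ct] = expressed[ct]
        else:
            # progenitor-independent types without expression data: PolII
            # follows an active promoter state
            pol_bound[ct] = states[ct].isin(["K4_only"]).to_numpy() & (
                rng.random(len(gene_ids)) < 0.5
            )

    # --- domains ------------------------------------------------------------
    rows: list[tuple] = []  # mark, cell_type, chrom, start, end, fold

    def centered(g: GeneModel, lo: int, hi: int) -> tuple[str, int, int]:
        length = int(rng.integers(lo, hi + 1))
        start = max(0, g.tss - length // 2)
        return g.interval.chrom, start, start + length

    for gid in gene_ids:
        g = gene_by_id[gid]
        for ct in config.cell_types:
            st = states.loc[gid, ct]
            if st in ("bivalent", "K4_only") and "H3K4me3" in config.marks:
                c, a, b = centered(g, *config.k4_domain_length)
                rows.append(("H3K4me3", ct, c, a, b,
                             config.enrichment_fold["H3K4me3"]))
            if st in ("bivalent", "K27_only") and "H3K27me3" in config.marks:
                c, a, b = centered(g, *config.k27_promoter_domain_length)
                rows.append(("H3K27me3", ct, c, a, b,
                             config.enrichment_fold["H3K27me3"]))
            if pol_bound.loc[gid, ct] and "PolII" in config.marks:
                c, a, b = centered(g, 800, 1500)
                rows.append(("PolII", ct, c, a, b,
                             config.enrichment_fold["PolII"]))
                if "BRG1" in config.marks:
                    c, a, b = centered(g, 1000, 2000)
                    rows.append(("BRG1", ct, c, a, b,
                                 config.enrichment_fold["BRG1"]))
            if (
                "H3K27me1" in config.marks
                and ct in config.expression_types
                and expressed.loc[gid, ct]
            ):
                iv = g.interval
                rows.append(("H3K27me1", ct, iv.chrom, iv.start, iv.end,
                             config.enrichment_fold["H3K27me1"]))

    placer = _Placer(genome, genes, rng)

    # distal H3K27me3 domains with cross-type presence patterns
    if "H3K27me3" in config.marks:
        n_types = len(config.cell_types)
        for _ in range(config.n_distal_k27_domains):
            length = int(rng.integers(*config.k27_distal_domain_length))
            spot = placer.place(length)
            if spot is None:
                continue
            c, a, b = spot
            u = rng.random()
            if u < 0.5:
                present = [config.cell_types[rng.integers(n_types)]]
            elif u < 0.8:
                k = int(rng.integers(2, n_types))
                present = list(
                    rng.choice(np.array(config.cell_types, dtype=object), k, False)
                )
            else:
                present = [t for t in config.cell_types if t != lineage.root]
            for ct in present:
                rows.append(("H3K27me3", ct, c, a, b,
                             config.enrichment_fold["H3K27me3"]))

    # --- enhancers -----------------------------------------------------------
    enh_rows: list[tuple] = []
    enh_types = list(config.expression_types)

    def enhancer_marks() -> tuple[bool, bool]:
        u = rng.random()
        if u < 0.6:
            return True, True
        if u < 0.8:
            return True, False
        return False, True

    for _ in range(config.n_cpe):
        length = int(rng.integers(*config.enhancer_length))
        spot = placer.place(length)
        if spot is None:
            continue
        c, a, b = spot
        h2az, k4me1 = enhancer_marks()
        enh_rows.append((c, a, b, "CPE", None, h2az, k4me1, None))
        for ct in enh_types:
            if h2az:
                rows.append(("H2A.Z", ct, c, a, b,
                             config.enrichment_fold["H2A.Z"]))
            if k4me1:
                rows.append(("H3K4me1", ct, c, a, b,
                             config.enrichment_fold["H3K4me1"]))

    for ct in enh_types:
        placed = 0
        # CSPEs planted upstream of this type's TS genes first
        for gid in ts_genes[ct]:
            g = gene_by_id[gid]
            for _ in range(config.cspe_per_ts_gene):
                if placed >= config.n_cspe_per_type:
                    break
                length = int(rng.integers(*config.enhancer_length))
                if g.strand == "+":
                    lo, hi = g.tss - 18000, g.tss - 3000 - length
                else:
                    lo, hi = g.tss + 3000, g.tss + 18000 - length
                spot = placer.place(length, chrom=g.interval.chrom, lo=lo, hi=hi)
                if spot is None:
                    continue
                c, a, b = spot
                h2az, k4me1 = enhancer_marks()
                enh_rows.append((c, a, b, "CSPE", ct, h2az, k4me1, gid))
                if h2az:
                    rows.append(("H2A.Z", ct, c, a, b,
                                 config.enrichment_fold["H2A.Z"]))
                if k4me1:
                    rows.append(("H3K4me1", ct, c, a, b,
                                 config.enrichment_fold["H3K4me1"]))
                placed += 1
        while placed < config.n_cspe_per_type:
            length = int(rng.integers(*config.enhancer_length))
            spot = placer.place(length)
            if spot is None:
                break
            c, a, b = spot
            h2az, k4me1 = enhancer_marks()
            enh_rows.append((c, a, b, "CSPE", ct, h2az, k4me1, None))
            if h2az:
                rows.append(("H2A.Z", ct, c, a, b, config.enrichment_fold["H2A.Z"]))
            if k4me1:
                rows.append(("H3K4me1", ct, c, a, b,
                             config.enrichment_fold["H3K4me1"]))
            placed += 1

    domains = pd.DataFrame(
        rows, columns=["mark", "cell_type", "chrom", "start", "end", "fold"]
    )
    enhancers = pd.DataFrame(
        enh_rows,
        columns=["chrom", "start", "end", "class", "cell_type",
                 "has_H2A.Z", "has_H3K4me1", "target_gene"],
    )

    # --- CpG islands conditioned on realized H3K4me3 consistency -------------
    blood = [t for t in config.expression_types if t in states.columns]
    k4_present = states[blood].isin(["bivalent", "K4_only"])
    consistent = k4_present.all(axis=1)
    cpg_rows = []
    for gid in gene_ids:
        p = config.p_cpg_consistent if consistent[gid] else config.p_cpg_other
        if rng.random() < p:
            g = gene_by_id[gid]
            half = int(rng.integers(300, 700))
            cpg_rows.append(
                (g.interval.chrom, max(0, g.tss - half), g.tss + half)
            )
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "start", "end"])
    if not cpg.empty:
        cpg = cpg.sort_values(["chrom", "start"]).reset_index(drop=True)
        cpg["start"] = cpg["start"].astype(np.int64)
        cpg["end"] = cpg["end"].astype(np.int64)

    return TruthManifest(
        config=config, genome=genome, genes=genes, cpg=cpg, states=states,
        domains=domains, enhancers=enhancers, ts_genes=ts_genes,
        expression_means=means, polII_bound=pol_bound,
    )


# ---------------------------------------------------------------------------
# Read and count simulation
# ---------------------------------------------------------------------------


def simulate_chip_reads(
    truth: TruthManifest,
    mark: str,
    cell_type: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw reads for one mark/cell-type library.

    Fragment-center positions follow a Poisson process at the background
    rate genome-wide plus ``(fold - 1) x background`` inside each planted
    domain (folds add where same-mark domains overlap).  Each read is a
    ``read_length`` fragment end placed ``fragment_size / 2`` from the
    sampled center, strand Bernoulli(1/2), so the standard strand-aware
    +/-75 bp shift re-centers it.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(_stream_seed(config.seed, f"{mark}|{cell_type}"))
    domains = (
        truth.domains_for(mark, cell_type)
        if mark != "input"
        else pd.DataFrame(columns=["chrom", "start", "end", "fold"])
    )
    half = config.fragment_size // 2
    frames = []
    for chrom, length in truth.genome.chrom_lengths.items():
        centers = [
            rng.uniform(0, length, rng.poisson(config.background_rate * length))
        ]
        for d in domains[domains["chrom"] == chrom].itertuples():
            extra_rate = config.background_rate * (d.fold - 1.0)
            n = rng.poisson(extra_rate * (d.end - d.start))
            centers.append(rng.uniform(d.start, d.end, n))
        pos = np.concatenate(centers).astype(np.int64)
        if pos.size == 0:
            continue
        strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
        start = np.where(
            strand == "+", pos - half, pos + half - config.read_length + 1
        )
        start = np.clip(start, 0, length - config.read_length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start.astype(np.int64),
                    "end": (start + config.read_length).astype(np.int64),
                    "strand": strand,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def simulate_expression(
    truth: TruthManifest,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial count table (genes x expression types).

    Counts have mean ``mu_g`` per gene (elevated ``ts_fold``-fold in the
    planted type-specific cell type only) and dispersion ``phi``
    (variance ``mu + phi mu^2``); ``phi = 0`` gives deterministic
    rounded means.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(_stream_seed(config.seed, "rna"))
    return nb_counts(truth.expression_means, config.dispersion, rng)


def nb_counts(
    means: pd.DataFrame, phi: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Negative-binomial counts (variance ``mu + phi mu^2``) per column."""
    counts = pd.DataFrame(index=means.index, columns=means.columns, dtype=np.int64)
    for ct in means.columns:
        mu = means[ct].to_numpy(dtype=float)
        if phi == 0:
            counts[ct] = np.round(mu).astype(np.int64)
        else:
            r = 1.0 / phi
            p = r / (r + mu)
            counts[ct] = rng.negative_binomial(r, p).astype(np.int64)
    return counts


def simulate_all(
    config: SimulationConfig,
) -> tuple[TruthManifest, dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Full deterministic simulation: truth, read sets, expression counts."""
    ss = np.random.SeedSequence(config.seed)
    keys = ["genome", "landscape", "rna"] + [
        f"{mark}|{ct}"
        for mark in list(config.marks) + ["input"]
        for ct in config.cell_types
    ]
    children = dict(zip(keys, ss.spawn(len(keys))))
    genome, genes = generate_genome(config, np.random.default_rng(children["genome"]))
    truth = plant_chromatin_landscape(
        genome, genes, config, np.random.default_rng(children["landscape"])
    )
    reads: dict[tuple[str, str], pd.DataFrame] = {}
    for mark in list(config.marks) + ["input"]:
        for ct in config.cell_types:
            reads[(mark, ct)] = simulate_chip_reads(
                truth, mark, ct, config,
                np.random.default_rng(children[f"{mark}|{ct}"]),
            )
    counts = simulate_expression(
        truth, config, np.random.default_rng(children["rna"])
    )
    return truth, reads, counts


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cell_types"] = list(d["cell_types"])
    d["marks"] = list(d["marks"])
    d["expression_types"] = list(d["expression_types"])
    d["lineage_edges"] = [list(e) for e in d["lineage_edges"]]
    for key in ("k4_domain_length", "k27_promoter_domain_length",
                "k27_distal_domain_length", "enhancer_length"):
        d[key] = list(d[key])
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["cell_types"] = tuple(d["cell_types"])
    d["marks"] = tuple(d["marks"])
    d["expression_types"] = tuple(d["expression_types"])
    d["lineage_edges"] = tuple(tuple(e) for e in d["lineage_edges"])
    for key in ("k4_domain_length", "k27_promoter_domain_length",
                "k27_distal_domain_length", "enhancer_length"):
        d[key] = tuple(d[key])
    return SimulationConfig(**d)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def manifest_to_dict(truth: TruthManifest) -> dict:
    df = truth.enhancers.copy()
    df = df.where(pd.notna(df), None)
    return {
        "config": _config_to_dict(truth.config),
        "chrom_lengths": dict(truth.genome.chrom_lengths),
        "effective_fraction": truth.genome.effective_fraction,
        "states": {c: truth.states[c].to_dict() for c in truth.states.columns},
        "domains": truth.domains.to_dict(orient="list"),
        "enhancers": df.to_dict(orient="list"),
        "ts_genes": truth.ts_genes,
        "expression_means": {
            c: truth.expression_means[c].to_dict()
            for c in truth.expression_means.columns
        },
        "polII_bound": {
            c: truth.polII_bound[c].astype(bool).to_dict()
            for c in truth.polII_bound.columns
        },
        "cpg": truth.cpg.to_dict(orient="list"),
    }


def manifest_from_dict(d: dict, genes: list[GeneModel]) -> TruthManifest:
    config = _config_from_dict(d["config"])
    genome = GenomeSpec(
        chrom_lengths=d["chrom_lengths"],
        effective_fraction=d["effective_fraction"],
    )
    gene_ids = [g.gene_id for g in genes]
    states = pd.DataFrame(d["states"]).reindex(gene_ids)
    domains = pd.DataFrame(d["domains"])
    enhancers = pd.DataFrame(d["enhancers"])
    means = pd.DataFrame(d["expression_means"]).reindex(gene_ids)
    pol = pd.DataFrame(d["polII_bound"]).reindex(gene_ids)
    cpg = pd.DataFrame(d["cpg"])
    if not cpg.empty:
        cpg["start"] = cpg["start"].astype(np.int64)
        cpg["end"] = cpg["end"].astype(np.int64)
    return TruthManifest(
        config=config, genome=genome, genes=genes, cpg=cpg, states=states,
        domains=domains, enhancers=enhancers,
        ts_genes={k: list(v) for k, v in d["ts_genes"].items()},
        expression_means=means, polII_bound=pol,
    )


def write_fixture_bundle(
    truth: TruthManifest,
    reads: Mapping[tuple[str, str], pd.DataFrame],
    expression_counts: pd.DataFrame,
    directory: str | Path,
) -> Path:
    """Write the complete synthetic input bundle in standard formats."""
    outdir = Path(directory)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(truth.genome.chrom_lengths, outdir / "genome.chrom.sizes")
    write_gene_annotation(truth.genes, outdir / "genes.bed12")
    write_bed_intervals(truth.cpg, outdir / "cpg_islands.bed")
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for (mark, ct), df in reads.items():
        safe = mark.replace(".", "")
        write_bed_reads(df, reads_dir / f"{safe}_{ct}.bed")
    expression_counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest_to_dict(truth), fh, indent=1, default=_json_default)
    return outdir


def load_fixture_bundle(
    directory: str | Path,
) -> tuple[TruthManifest, dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Round-trip loader for :func:`write_fixture_bundle` output."""
    outdir = Path(directory)
    genes = read_gene_annotation(outdir / "genes.bed12")
    with open(outdir / "manifest.json") as fh:
        truth = manifest_from_dict(json.load(fh), genes)
    reads: dict[tuple[str, str], pd.DataFrame] = {}
    for path in sorted((outdir / "reads").glob("*.bed")):
        stem = path.stem
        name, ct = stem.rsplit("_", 1)
        mark = {m.replace(".", ""): m for m in list(truth.config.marks) + ["input"]}[
            name
        ]
        reads[(mark, ct)] = read_bed_reads(path)
    counts = pd.read_csv(outdir / "expression_counts.tsv", sep="\t", index_col=0)
    return truth, reads, counts
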