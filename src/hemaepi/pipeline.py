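"""End-to-end orchestration of the comparison pipeline on an input bundle.

Stages run in dependency order: island calling per mark and cell type
(against the matched input control), then promoter states with lineage
resolution/establishment tables, enhancer catalog with gene association,
H3K27me3 domain dynamics, expression (RPKM, pairwise DE, type-specific
genes), and metaprofiles.  Every stage writes its outputs as plain-text
tables under the output directory, and a JSON run manifest records
parameters and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import domains as domains_mod
from . import enhancers as enh_mod
from . import expression as expr_mod
from . import profiles as prof_mod
from .core import (
    GenomeSpec,
    deduplicate_reads,
    read_bed_reads,
    read_bed_intervals,
    read_chrom_sizes,
    read_gene_annotation,
)
from .islands import (
    CallerConfig,
    DEFAULT_MARK_CONFIGS,
    call_and_filter,
    islands_to_frame,
    polII_gene_binding,
    write_islands_bed,
)
from .promoters import (
    LineageTree,
    bivalency_membership_matrix,
    establishment_matrix,
    resolution_matrix,
    state_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated run configuration (usually loaded from YAML)."""

    chrom_sizes: str
    annotation: str
    cpg_islands: str
    read_files: dict[str, dict[str, str]]   # mark -> cell type -> BED path
    expression_counts: str                  # TSV gene x cell type
    lineage_edges: list[tuple[str, str]]
    output_dir: str
    effective_fraction: float = 1.0
    caller_configs: dict[str, CallerConfig] = field(default_factory=dict)
    lfc_min: float = 5.0
    de_fdr: float = 1e-5
    promoter_flank: int = 500
    assoc_flank: int = 20000
    fragment_max: int = 2000
    kmeans_k: int = 20
    seed: int = 0
    nibble: bool = True
    drop_chrY: bool = True

    def caller_for(self, mark: str) -> CallerConfig:
        if mark in self.caller_configs:
            return self.caller_configs[mark]
        return DEFAULT_MARK_CONFIGS.get(mark, CallerConfig())


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    callers = {
        mark: CallerConfig(**vals)
        for mark, vals in raw.pop("caller_configs", {}).items()
    }
    edges = [tuple(e) for e in raw.pop("lineage_edges")]
    return PipelineConfig(lineage_edges=edges, caller_configs=callers, **raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the list of violations (empty means the config is valid)."""
    problems: list[str] = []
    for name in ("chrom_sizes", "annotation", "cpg_islands", "expression_counts"):
        path = getattr(config, name)
        if not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    for mark, per_type in config.read_files.items():
        for ct, path in per_type.items():
            if not Path(path).exists():
                problems.append(f"read_files.{mark}.{ct}: file not found: {path}")
    if not (0 < config.de_fdr < 1):
        problems.append("de_fdr must be in (0, 1)")
    try:
        LineageTree(edges=tuple(config.lineage_edges))
    except ValueError as exc:
        problems.append(f"lineage_edges: {exc}")
    if not (0 < config.effective_fraction <= 1):
        problems.append("effective_fraction must be in (0, 1]")
    return problems


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with the stage name in the exception and
    leaves a ``FAILED`` marker beside the partial outputs.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k != "caller_configs"
        },
        "caller_configs": {
            m: dataclasses.asdict(config.caller_for(m))
            for m in config.read_files
        },
        "inputs": {},
        "stages": {},
    }
    stage = "load-inputs"
    try:
        genome = GenomeSpec(
            chrom_lengths=read_chrom_sizes(config.chrom_sizes),
            effective_fraction=config.effective_fraction,
        )
        genes = read_gene_annotation(config.annotation, drop_chrY=config.drop_chrY)
        cpg = read_bed_intervals(config.cpg_islands)
        counts = pd.read_csv(config.expression_counts, sep="\t", index_col=0)
        manifest["inputs"] = {
            "chrom_sizes": _checksum(config.chrom_sizes),
            "annotation": _checksum(config.annotation),
            "expression_counts": _checksum(config.expression_counts),
        }
        cell_types = sorted({ct for per in config.read_files.values() for ct in per})
        lineage = LineageTree(edges=tuple(config.lineage_edges))

        stage = "call-islands"
        islands_by = _call_all_islands(config, genome, manifest)
        isl_frames = {
            mark: {ct: islands_to_frame(isls) for ct, isls in per.items()}
            for mark, per in islands_by.items()
        }

        stage = "promoter-states"
        state_types = [
            ct for ct in cell_types
            if ct in isl_frames.get("H3K4me3", {}) and ct in isl_frames.get("H3K27me3", {})
        ]
        states = state_table(
            genes,
            {ct: {"H3K4me3": isl_frames["H3K4me3"][ct],
                  "H3K27me3": isl_frames["H3K27me3"][ct]}
             for ct in state_types},
            flank=config.promoter_flank,
        )
        states.to_csv(outdir / "promoter_states.tsv", sep="\t")
        bivalency_membership_matrix(states).to_csv(
            outdir / "bivalency_membership.tsv", sep="\t"
        )
        for node in lineage.nodes:
            children = lineage.children_of(node)
            if children and node in states.columns:
                usable = [c for c in children if c in states.columns]
                if usable:
                    resolution_matrix(states, lineage, node, usable).to_csv(
                        outdir / f"bivalency_resolution_{node}.tsv", sep="\t"
                    )
        est = {}
        for node in lineage.nodes:
            parent = lineage.parent_of(node)
            if parent and node in states.columns and parent in states.columns:
                est[node] = establishment_matrix(states, lineage, node)
        if est:
            pd.DataFrame(est).to_csv(
                outdir / "bivalency_establishment.tsv", sep="\t"
            )
        if "PolII" in isl_frames:
            pol = pd.DataFrame(
                {
                    ct: [polII_gene_binding(g, frame) for g in genes]
                    for ct, frame in isl_frames["PolII"].items()
                },
                index=[g.gene_id for g in genes],
            )
            pol.to_csv(outdir / "polII_bound.tsv", sep="\t")

        stage = "expression"
        lib_sizes = counts.sum(axis=0)
        exon_lengths = pd.Series(
            {g.gene_id: g.exon_length for g in genes}
        ).reindex(counts.index)
        rpkm = expr_mod.rpkm_table(counts, exon_lengths, lib_sizes)
        rpkm.to_csv(outdir / "rpkm.tsv", sep="\t")
        de = expr_mod.all_pairwise_de(
            counts, lib_sizes, lfc_min=config.lfc_min, fdr_max=config.de_fdr
        )
        ts: dict[str, list[str]] = {}
        expr_types = list(counts.columns)
        for ct in expr_types:
            others = [o for o in expr_types if o != ct]
            ts[ct] = sorted(expr_mod.type_specific_genes(de, ct, others))
        with open(outdir / "type_specific_genes.json", "w") as fh:
            json.dump(ts, fh, indent=1)

        stage = "enhancers"
        enh_types = [
            ct for ct in expr_types
            if ct in isl_frames.get("H2A.Z", {}) and ct in isl_frames.get("H3K4me1", {})
        ]
        catalog = pd.DataFrame()
        if len(enh_types) >= 2:
            candidates = {
                ct: enh_mod.predict_enhancers(
                    isl_frames["H2A.Z"][ct], isl_frames["H3K4me1"][ct], genes,
                    exclusion_flank=config.promoter_flank,
                )
                for ct in enh_types
            }
            catalog = enh_mod.build_catalog(candidates)
            catalog = enh_mod.associate_catalog(
                catalog, genes, flank=config.assoc_flank,
                promoter_margin=config.promoter_flank,
            )
            if "H3K27me3" in isl_frames:
                biv = np.zeros(len(catalog), dtype=bool)
                for ct in enh_types:
                    if ct in isl_frames["H3K27me3"]:
                        biv |= np.asarray(
                            enh_mod.overlaps_any(
                                catalog, isl_frames["H3K27me3"][ct]
                            )
                        )
                catalog["bivalent"] = biv
            catalog.to_csv(outdir / "enhancer_catalog.tsv", sep="\t", index=False)
            ks_rows = []
            for ct in enh_types:
                expressed = set(rpkm.index[rpkm[ct] > 0])
                if ts[ct] and expressed:
                    cmp_ = enh_mod.cspe_count_comparison(
                        catalog, set(ts[ct]), expressed, ct
                    )
                    ks_rows.append(
                        (ct, cmp_.statistic, cmp_.p_value,
                         float(cmp_.values_a.mean()), float(cmp_.values_b.mean()))
                    )
            pd.DataFrame(
                ks_rows,
                columns=["cell_type", "ks_stat", "ks_p",
                         "mean_cspe_ts_genes", "mean_cspe_all_genes"],
            ).to_csv(outdir / "cspe_expression_association.tsv", sep="\t",
                     index=False)

        stage = "domain-dynamics"
        if "H3K27me3" in isl_frames:
            k27 = isl_frames["H3K27me3"]
            size_rows = []
            for ct, frame in k27.items():
                if frame.empty:
                    continue
                s = domains_mod.island_size_stats(frame)
                size_rows.append(
                    (ct, s["n_islands"], s["modal_size"], s["median_size"],
                     s["total_bp"],
                     domains_mod.genome_coverage(frame, genome))
                )
            pd.DataFrame(
                size_rows,
                columns=["cell_type", "n_islands", "modal_size", "median_size",
                         "total_bp", "genome_coverage"],
            ).to_csv(outdir / "k27_domain_summary.tsv", sep="\t", index=False)
            frags = domains_mod.unify_and_fragment(
                list(k27.values()), max_fragment=config.fragment_max
            )
            if not frags.empty:
                reads_k27 = {
                    ct: _load_reads(config, "H3K27me3", ct)
                    for ct in k27
                }
                matrix = domains_mod.fragment_read_matrix(
                    frags, reads_k27,
                    {ct: len(df) for ct, df in reads_k27.items()},
                )
                k = min(config.kmeans_k, len(frags))
                matrix = matrix.set_index(
                    pd.Index(range(len(matrix)), name="fragment")
                )
                clusters = domains_mod.cluster_fragments(
                    matrix, k=k, seed=config.seed
                )
                out = pd.concat(
                    [frags.reset_index(drop=True), matrix.reset_index(drop=True)],
                    axis=1,
                )
                out["cluster_id"] = clusters.to_numpy()
                out.to_csv(outdir / "k27_fragment_matrix.tsv", sep="\t",
                           index=False)
        if "H3K4me3" in isl_frames and not cpg.empty:
            k4_presence = pd.DataFrame(
                {
                    ct: states[ct].isin(["bivalent", "K4_only"])
                    for ct in state_types if ct != lineage.root
                }
            )
            domains_mod.h3k4me3_consistency_cpg(
                k4_presence, genes, cpg, flank=config.promoter_flank
            ).to_csv(outdir / "k4_consistency_cpg.tsv", sep="\t")

        stage = "profiles"
        pconf = prof_mod.ProfileConfig()
        anchors = prof_mod.tss_anchor_frame(genes)
        prof_rows = {}
        for mark in ("H3K4me3", "H3K27me3"):
            if mark not in isl_frames:
                continue
            for ct, frame in isl_frames[mark].items():
                reads = _load_reads(config, mark, ct)
                lib = len(reads)
                if pconf.island_filter:
                    reads = prof_mod.filter_reads_to_islands(
                        reads, frame, pconf.shift
                    )
                if lib:
                    prof_rows[f"{mark}:{ct}"] = prof_mod.tss_profile(
                        reads, anchors, pconf, lib
                    )
        if prof_rows:
            pd.DataFrame(prof_rows).to_csv(outdir / "tss_profiles.tsv", sep="\t")

        manifest["stages"]["all"] = {"status": "ok"}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir


def _load_reads(config: PipelineConfig, mark: str, cell_type: str) -> pd.DataFrame:
    path = config.read_files[mark][cell_type]
    return deduplicate_reads(read_bed_reads(path, drop_chrY=config.drop_chrY))


def _call_all_islands(
    config: PipelineConfig, genome: GenomeSpec, manifest: dict
) -> Mapping[str, Mapping[str, list]]:
    outdir = Path(config.output_dir)
    (outdir / "islands").mkdir(exist_ok=True)
    results: dict[str, dict[str, list]] = {}
    for mark, per_type in config.read_files.items():
        if mark == "input":
            continue
        results[mark] = {}
        for ct in per_type:
            reads = _load_reads(config, mark, ct)
            control = None
            if "input" in config.read_files and ct in config.read_files["input"]:
                control = _load_reads(config, "input", ct)
            caller = config.caller_for(mark)
            isls = call_and_filter(
                reads, control, caller, genome, nibble=config.nibble
            )
            results[mark][ct] = isls
            safe = mark.replace(".", "")
            write_islands_bed(isls, outdir / "islands" / f"{safe}_{ct}.bed")
            logger.info("%s/%s: %d islands", mark, ct, len(isls))
    return results
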