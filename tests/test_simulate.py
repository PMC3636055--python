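"""Synthetic-data generator: determinism, planted-truth consistency, I/O."""

import numpy as np
import pandas as pd
import pytest

from hemaepi.simulate import (
    SimulationConfig,
    generate_genome,
    load_fixture_bundle,
    nb_counts,
    plant_chromatin_landscape,
    plant_expression,
    simulate_all,
    simulate_chip_reads,
    write_fixture_bundle,
)


SMALL = dict(
    n_chroms=1, chrom_length=2_000_000, n_genes=50,
    n_distal_k27_domains=10, n_cpe=8, n_cspe_per_type=5,
    ts_genes_per_type=3,
)


class TestGenome:
    def test_zero_genes_still_valid(self):
        genome, genes = generate_genome(SimulationConfig(n_genes=0))
        assert genes == [] and genome.total_length > 0

    def test_same_seed_identical_output(self):
        a = generate_genome(SimulationConfig(seed=5, **SMALL))
        b = generate_genome(SimulationConfig(seed=5, **SMALL))
        assert a == b

    def test_tss_never_collide(self):
        _, genes = generate_genome(SimulationConfig(seed=2, **SMALL))
        tss = [(g.interval.chrom, g.tss) for g in genes]
        assert len(set(tss)) == len(tss)

    def test_too_dense_errors(self):
        with pytest.raises(ValueError, match="do not fit"):
            generate_genome(
                SimulationConfig(n_chroms=1, chrom_length=100_000, n_genes=50)
            )


class TestLandscape:
    def test_identity_transitions_freeze_states(self):
        identity = {
            s: {t: (1.0 if t == s else 0.0)
                for t in ("bivalent", "K4_only", "K27_only", "none")}
            for s in ("bivalent", "K4_only", "K27_only", "none")
        }
        config = SimulationConfig(seed=7, transition_probs=identity, **SMALL)
        genome, genes = generate_genome(config)
        truth = plant_chromatin_landscape(genome, genes, config)
        for ct in config.cell_types:
            assert (truth.states[ct] == truth.states["ESC"]).all()

    def test_forced_resolution_eliminates_bivalency(self):
        probs = {
            "bivalent": {"bivalent": 0.0, "K4_only": 1.0, "K27_only": 0.0,
                         "none": 0.0},
            "K4_only": {"bivalent": 0.0, "K4_only": 1.0, "K27_only": 0.0,
                        "none": 0.0},
            "K27_only": {"bivalent": 0.0, "K4_only": 0.0, "K27_only": 1.0,
                         "none": 0.0},
            "none": {"bivalent": 0.0, "K4_only": 0.0, "K27_only": 0.0,
                     "none": 1.0},
        }
        config = SimulationConfig(seed=7, transition_probs=probs, **SMALL)
        genome, genes = generate_genome(config)
        truth = plant_chromatin_landscape(genome, genes, config)
        for ct in ("HSPC", "pRBC", "T", "B"):
            assert (truth.states[ct] != "bivalent").all()

    def test_empirical_transition_frequencies_match_config(self):
        """Law-of-large-numbers check on the bivalent row, 2000 genes."""
        config = SimulationConfig(
            seed=9, n_chroms=1, chrom_length=60_000_000, n_genes=2000,
            n_distal_k27_domains=0, n_cpe=0, n_cspe_per_type=0,
            ts_genes_per_type=0,
        )
        genome, genes = generate_genome(config)
        truth = plant_chromatin_landscape(genome, genes, config)
        parent_biv = truth.states.index[truth.states["HSPC"] == "bivalent"]
        fates = truth.states.loc[parent_biv, "T"].value_counts(normalize=True)
        for state, p in config.transition_probs["bivalent"].items():
            assert abs(fates.get(state, 0.0) - p) < 0.05

    def test_truth_is_internally_consistent(self, small_sim):
        truth, _, _ = small_sim
        truth.validate()

    def test_every_category_represented(self, small_sim):
        """The default transition structure exercises each resolution and
        establishment category on at least one lineage edge."""
        truth, _, _ = small_sim
        states = truth.states
        biv = states["HSPC"] == "bivalent"
        fates = set(states.loc[biv, "T"]) | set(states.loc[biv, "B"]) | set(
            states.loc[biv, "pRBC"]
        )
        assert fates == {"bivalent", "K4_only", "K27_only", "none"}
        enh = truth.enhancers
        assert (enh["class"] == "CPE").any()
        assert (enh["class"] == "CSPE").any()


class TestChipReads:
    def test_background_rate_recovered_at_fold_one(self):
        config = SimulationConfig(seed=3, **SMALL)
        genome, genes = generate_genome(config)
        truth = plant_chromatin_landscape(genome, genes, config)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            reads = simulate_chip_reads(truth, "input", "HSPC", config, rng)
            expected = config.background_rate * genome.total_length
            se = np.sqrt(expected)
            assert abs(len(reads) - expected) < 3 * se

    def test_zero_background_confines_reads_to_domain(self):
        config = SimulationConfig(seed=3, background_rate=1e-12, **SMALL)
        genome, genes = generate_genome(config)
        truth = plant_chromatin_landscape(genome, genes, config)
        reads = simulate_chip_reads(truth, "H3K27me3", "HSPC", config,
                                    np.random.default_rng(0))
        doms = truth.domains_for("H3K27me3", "HSPC")
        pad = config.fragment_size // 2
        ok = np.zeros(len(reads), bool)
        for d in doms.itertuples():
            ok |= (
                (reads["chrom"] == d.chrom)
                & (reads["start"] >= d.start - pad)
                & (reads["end"] <= d.end + pad + config.read_length)
            ).to_numpy()
        assert ok.all()

    def test_doubled_depth_doubles_counts(self):
        base = SimulationConfig(seed=3, **SMALL)
        double = SimulationConfig(
            seed=3, **{**SMALL, "n_genes": SMALL["n_genes"]},
        )
        genome, genes = generate_genome(base)
        truth = plant_chromatin_landscape(genome, genes, base)
        n1 = np.mean([
            len(simulate_chip_reads(truth, "input", "T", base,
                                    np.random.default_rng(s)))
            for s in range(3)
        ])
        double = SimulationConfig(
            seed=3, background_rate=2 * base.background_rate, **SMALL
        )
        n2 = np.mean([
            len(simulate_chip_reads(truth, "input", "T", double,
                                    np.random.default_rng(s)))
            for s in range(3)
        ])
        se = np.sqrt(n2)
        assert abs(n2 - 2 * n1) < 3 * se

    def test_same_rng_seed_identical_reads(self):
        config = SimulationConfig(seed=3, **SMALL)
        genome, genes = generate_genome(config)
        truth = plant_chromatin_landscape(genome, genes, config)
        a = simulate_chip_reads(truth, "H3K4me3", "B", config,
                                np.random.default_rng(1))
        b = simulate_chip_reads(truth, "H3K4me3", "B", config,
                                np.random.default_rng(1))
        pd.testing.assert_frame_equal(a, b)


class TestExpressionSim:
    def test_zero_dispersion_is_deterministic_means(self):
        config = SimulationConfig(seed=1, dispersion=0.0, **SMALL)
        gene_ids = [f"g{i}" for i in range(100)]
        means, ts = plant_expression(gene_ids, config,
                                     np.random.default_rng(0))
        counts = nb_counts(means, 0.0, np.random.default_rng(1))
        assert (counts.to_numpy() == np.round(means.to_numpy())).all()
        for ct, genes in ts.items():
            for g in genes:
                others = [c for c in counts.columns if c != ct]
                assert (counts.loc[g, ct] >= 32 * (counts.loc[g, others] + 1)).all()

    def test_same_seed_identical_table(self):
        config = SimulationConfig(seed=1, **SMALL)
        gene_ids = [f"g{i}" for i in range(100)]
        means, _ = plant_expression(gene_ids, config, np.random.default_rng(0))
        a = nb_counts(means, config.dispersion, np.random.default_rng(2))
        b = nb_counts(means, config.dispersion, np.random.default_rng(2))
        pd.testing.assert_frame_equal(a, b)


class TestBundle:
    def test_round_trip(self, small_sim, tmp_path):
        truth, reads, counts = small_sim
        write_fixture_bundle(truth, reads, counts, tmp_path / "bundle")
        truth2, reads2, counts2 = load_fixture_bundle(tmp_path / "bundle")
        pd.testing.assert_frame_equal(truth.states, truth2.states)
        pd.testing.assert_frame_equal(
            truth.domains, truth2.domains, check_dtype=False
        )
        assert truth.ts_genes == truth2.ts_genes
        assert truth.config == truth2.config
        assert [g.gene_id for g in truth.genes] == [
            g.gene_id for g in truth2.genes
        ]
        key = ("H3K4me3", "HSPC")
        pd.testing.assert_frame_equal(reads[key], reads2[key])
        pd.testing.assert_frame_equal(counts, counts2, check_dtype=False)

    def test_full_simulation_deterministic(self):
        cfg = SimulationConfig(seed=21, **SMALL,
                               marks=("H3K4me3", "H3K27me3"))
        t1, r1, c1 = simulate_all(cfg)
        t2, r2, c2 = simulate_all(cfg)
        pd.testing.assert_frame_equal(t1.states, t2.states)
        pd.testing.assert_frame_equal(r1[("H3K27me3", "T")],
                                      r2[("H3K27me3", "T")])
        pd.testing.assert_frame_equal(c1, c2)
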