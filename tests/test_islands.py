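"""Island caller: eligibility, gap joining, significance, nibbling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemaepi.core import GenomeSpec
from hemaepi.islands import (
    CallerConfig,
    Island,
    WindowCounts,
    assess_significance,
    background_rate,
    call_islands,
    count_windows,
    eligibility_threshold,
    nibble_island,
    polII_gene_binding,
)

from conftest import intervals_frame, make_gene, reads_frame


def poisson_tail_oracle(k: int, lam: float) -> float:
    """P(X >= k) by direct upper-tail pmf summation (no library tail calls).

    Summing the upper tail term by term avoids the cancellation of
    ``1 - sum(lower pmf)``; the leading term is computed in log space.
    """
    if k <= 0:
        return 1.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > total * 1e-17 + 1e-320:
        total += term
        i += 1
        term *= lam / i
    return total


def brute_force_islands(counts: np.ndarray, threshold: int, gap: int):
    """Enumerate every window; join eligible runs bridging <= gap windows."""
    eligible = [i for i, c in enumerate(counts) if c >= threshold]
    runs = []
    for i in eligible:
        if runs and i - runs[-1][-1] - 1 <= gap:
            runs[-1].append(i)
        else:
            runs.append([i])
    return [(r[0], r[-1]) for r in runs]


class TestEligibility:
    def test_small_rate_allows_single_read(self):
        # P(X>=1 | 0.2) = 1 - e^-0.2 ~ 0.1813 < 0.2
        assert eligibility_threshold(0.2, 0.2) == 1

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("p", [0.2, 0.05])
    def test_matches_pmf_summation_oracle(self, lam, p):
        k = eligibility_threshold(lam, p)
        assert poisson_tail_oracle(k, lam) < p
        assert k == 1 or poisson_tail_oracle(k - 1, lam) >= p

    def test_k_is_at_least_one(self):
        # the tail at 0 is always 1, so even permissive p forces k >= 1
        assert eligibility_threshold(5.0, 0.999) >= 1


class TestCountWindows:
    def test_fragment_shift_places_read_in_window(self, small_genome):
        config = CallerConfig(window=200, fragment_size=150)
        reads = reads_frame([("chr1", 100, 125, "+")])
        wc = count_windows(reads, config, small_genome)
        assert wc.counts["chr1"][0] == 1  # 100 + 75 = 175 -> window [0, 200)

    def test_minus_read_shifts_back(self, small_genome):
        config = CallerConfig(window=200, fragment_size=150)
        reads = reads_frame([("chr1", 375, 400, "-")])
        wc = count_windows(reads, config, small_genome)
        assert wc.counts["chr1"][1] == 1  # 399 - 75 = 324 -> window [200, 400)

    def test_counts_sum_to_reads(self, small_genome):
        rng = np.random.default_rng(5)
        reads = reads_frame(
            [
                ("chr1", int(s), int(s) + 25, "+")
                for s in rng.integers(0, 99_000, 500)
            ]
        )
        wc = count_windows(reads, CallerConfig(), small_genome)
        assert wc.counts["chr1"].sum() == 500

    def test_zero_reads_zero_counts(self, small_genome):
        wc = count_windows(reads_frame([]), CallerConfig(), small_genome)
        assert wc.counts["chr1"].sum() == 0


class TestCallIslands:
    def _counts(self, arr, genome):
        return WindowCounts(
            window=200,
            counts={"chr1": np.asarray(arr, dtype=np.int64)},
            total_reads=int(np.sum(arr)),
        )

    def test_gap_two_bridges_indices_3_4_7(self, small_genome):
        arr = np.zeros(20, dtype=int)
        arr[[3, 4, 7]] = 5
        cfg = CallerConfig(window=200, gap_windows=2)
        isls = call_islands(self._counts(arr, small_genome), cfg, small_genome,
                            bg_rate=0.5)
        assert [(i.start, i.end) for i in isls] == [(600, 1600)]

    def test_gap_one_splits_indices_3_4_7(self, small_genome):
        arr = np.zeros(20, dtype=int)
        arr[[3, 4, 7]] = 5
        cfg = CallerConfig(window=200, gap_windows=1)
        isls = call_islands(self._counts(arr, small_genome), cfg, small_genome,
                            bg_rate=0.5)
        assert [(i.start, i.end) for i in isls] == [(600, 1000), (1400, 1600)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        """Random instances <= 1000 windows match exhaustive enumeration,
        including scores to 1e-9."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 1000))
        lam = float(rng.uniform(0.3, 2.0))
        counts = rng.poisson(lam, size=n)
        # plant some enriched stretches
        for _ in range(rng.integers(1, 5)):
            a = int(rng.integers(0, n - 10))
            counts[a : a + int(rng.integers(3, 10))] += rng.poisson(
                5 * lam, size=1
            )
        gap = int(rng.integers(0, 4))
        genome = GenomeSpec(chrom_lengths={"chr1": n * 200},
                            effective_fraction=1.0)
        cfg = CallerConfig(window=200, gap_windows=gap)
        wc = WindowCounts(window=200, counts={"chr1": counts.astype(np.int64)},
                          total_reads=int(counts.sum()))
        bg = background_rate(wc.total_reads, cfg, genome)
        threshold = eligibility_threshold(bg, cfg.eligibility_p)
        expected = brute_force_islands(counts, threshold, gap)
        got = call_islands(wc, cfg, genome)
        assert [(i.start // 200, i.end // 200 - 1) for i in got] == expected
        for isl, (first, last) in zip(got, expected):
            span = counts[first : last + 1]
            score = sum(
                -math.log(poisson_tail_oracle(int(c), bg))
                for c in span
                if c >= threshold
            )
            assert isl.score == pytest.approx(score, abs=1e-9)
            assert isl.read_count == span.sum()

    def test_adding_reads_inside_island_never_removes_it(self, small_genome):
        arr = np.zeros(50, dtype=np.int64)
        arr[10:15] = 4
        cfg = CallerConfig(window=200, gap_windows=1)
        before = call_islands(
            WindowCounts(200, {"chr1": arr}, int(arr.sum())), cfg,
            small_genome, bg_rate=0.5,
        )
        arr2 = arr.copy()
        arr2[12] += 10
        after = call_islands(
            WindowCounts(200, {"chr1": arr2}, int(arr2.sum())), cfg,
            small_genome, bg_rate=0.5,
        )
        spans_before = {(i.start, i.end) for i in before}
        spans_after = {(i.start, i.end) for i in after}
        assert spans_before <= spans_after


class TestSignificance:
    def _wc(self, per_window, total=None):
        arr = np.asarray(per_window, dtype=np.int64)
        return WindowCounts(200, {"chr1": arr},
                            int(total if total is not None else arr.sum()))

    def test_scaled_poisson_tail_against_direct_summation(self):
        # chip 50 vs control 5 at equal library sizes
        isl = Island("chr1", 0, 200, read_count=50, score=10.0)
        chip = self._wc([50], total=1000)
        ctrl = self._wc([5], total=1000)
        cfg = CallerConfig(fdr=0.5)
        out = assess_significance([isl], chip, ctrl, cfg)
        expected_p = poisson_tail_oracle(50, 5.0)
        assert out[0].p_value == pytest.approx(expected_p, rel=1e-9)

    def test_equal_pvalues_give_equal_qvalues(self):
        isls = [
            Island("chr1", i * 200, (i + 1) * 200, read_count=30, score=5.0)
            for i in range(4)
        ]
        chip = self._wc([30, 30, 30, 30], total=400)
        ctrl = self._wc([3, 3, 3, 3], total=400)
        out = assess_significance(isls, chip, ctrl, CallerConfig(fdr=0.5))
        qs = {i.q_value for i in out}
        assert len(qs) == 1
        assert qs.pop() == pytest.approx(out[0].p_value)

    def test_zero_read_island_is_a_contradiction(self):
        isl = Island("chr1", 0, 200, read_count=0, score=0.0)
        with pytest.raises(ValueError):
            assess_significance([isl], self._wc([0]), self._wc([1]),
                                CallerConfig())

    def test_raising_fdr_never_yields_fewer_islands(self):
        rng = np.random.default_rng(7)
        chip_arr = rng.poisson(3.0, 30) + 5
        ctrl_arr = rng.poisson(1.0, 30)
        isls = [
            Island("chr1", i * 200, (i + 1) * 200,
                   read_count=int(chip_arr[i]), score=1.0)
            for i in range(30)
        ]
        chip = self._wc(chip_arr)
        ctrl = self._wc(ctrl_arr)
        n_prev = -1
        for fdr in (1e-8, 1e-4, 1e-2, 0.5):
            out = assess_significance(isls, chip, ctrl, CallerConfig(fdr=fdr))
            assert len(out) >= n_prev
            n_prev = len(out)

    def test_no_control_falls_back_to_evalue_mode(self, small_genome):
        isl = Island("chr1", 0, 400, read_count=40, score=20.0)
        chip = self._wc([20, 20], total=500)
        out = assess_significance([isl], chip, None, CallerConfig(),
                                  genome=small_genome)
        assert len(out) == 1 and out[0].p_value is not None


class TestNibbling:
    def test_uniform_edge_window_is_not_cut(self):
        cfg = CallerConfig(window=200)
        pos = np.arange(5, 600, 10)  # uniform density across 3 windows
        isl = Island("chr1", 0, 600, read_count=len(pos), score=5.0)
        out = nibble_island(isl, pos, cfg)
        assert (out.start, out.end) == (0, 600)

    def test_half_empty_edge_window_cut_at_boundary(self):
        """Left window [0,200) with all its reads in [100,200) trims at 100."""
        cfg = CallerConfig(window=200)
        left = np.arange(100, 200, 10)          # 10 reads in [100, 200)
        body = np.arange(205, 600, 5)           # dense interior
        pos = np.concatenate([left, body])
        isl = Island("chr1", 0, 600, read_count=len(pos), score=5.0)
        out = nibble_island(isl, pos, cfg)
        assert out.start == 100
        assert out.read_count == len(pos)

    def test_exhaustive_scan_agrees_on_first_cut(self):
        """The chosen left cut maximizes the density contrast over all
        19 candidate cuts (independent exhaustive re-computation)."""
        cfg = CallerConfig(window=200)
        rng = np.random.default_rng(2)
        pos = np.sort(
            np.concatenate([
                rng.integers(120, 200, 12),
                rng.integers(200, 1000, 120),
            ])
        )
        isl = Island("chr1", 0, 1000, read_count=len(pos), score=5.0)
        out = nibble_island(isl, pos, cfg)
        mean_density = len(pos) / 1000
        best_cut, best_diff = None, 0.0
        for cut in range(10, 200, 10):
            removed = (pos < cut).sum() / cut
            retained = ((pos >= cut) & (pos < 200)).sum() / (200 - cut)
            if retained - removed > best_diff and removed < mean_density:
                best_cut, best_diff = cut, retained - removed
        assert best_cut is not None
        assert out.start >= best_cut  # first cut, possibly refined further

    @pytest.mark.parametrize("seed", range(15))
    def test_properties_on_random_islands(self, seed):
        """Output within input; density never decreases when trimmed;
        idempotent."""
        rng = np.random.default_rng(seed)
        n_windows = int(rng.integers(2, 8))
        length = n_windows * 200
        pos = rng.integers(0, length, size=int(rng.integers(10, 200)))
        cfg = CallerConfig(window=200)
        isl = Island("chr1", 0, length,
                     read_count=len(pos), score=1.0)
        out = nibble_island(isl, pos, cfg)
        assert 0 <= out.start < out.end <= length
        if (out.start, out.end) != (0, length):
            dens_before = len(pos) / length
            inside = ((pos >= out.start) & (pos < out.end)).sum()
            assert inside / (out.end - out.start) >= dens_before
        again = nibble_island(out, pos, cfg)
        assert (again.start, again.end) == (out.start, out.end)


class TestPolIIBinding:
    def test_plus_strand_window(self):
        gene = make_gene("g", start=10_000, end=20_000, strand="+")
        assert polII_gene_binding(gene, intervals_frame([("chr1", 5200, 5400)]))
        assert not polII_gene_binding(
            gene, intervals_frame([("chr1", 23_001, 23_200)])
        )

    def test_minus_strand_upstream_extends_right(self):
        gene = make_gene("g", start=10_000, end=20_000, strand="-")
        assert polII_gene_binding(
            gene, intervals_frame([("chr1", 22_900, 23_100)])
        )
        assert not polII_gene_binding(
            gene, intervals_frame([("chr2", 12_000, 12_100)])
        )
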