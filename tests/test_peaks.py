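"""Density estimation, scoring, log-space significance, and the strict filters."""

import numpy as np
import pytest
from scipy import stats

from stat5kit.core_io import GenomicInterval, TagCollection
from stat5kit.peaks import (
    Peak,
    bh_log10_qvalues,
    call_candidate_peaks,
    call_peaks,
    estimate_density,
    finalize_peaks,
    poisson_log10_sf,
    score_peak,
    write_peaks_bed,
)

from conftest import uniform_tags


class TestPoissonLog10Sf:
    def test_matches_scipy_where_scipy_is_finite(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mu = float(rng.uniform(0.1, 50))
            k = int(rng.integers(0, 200))
            ref = stats.poisson.logsf(k - 1, mu) / np.log(10)
            if np.isfinite(ref):
                assert poisson_log10_sf(k, mu) == pytest.approx(ref, rel=1e-12)

    def test_deep_tail_stays_finite_beyond_underflow(self):
        # scipy's linear-scale sf underflows here; the log-space value must not
        val = poisson_log10_sf(1000, 4.1)
        assert np.isfinite(val)
        assert val < -1900  # far below the float64 underflow exponent (~-308)

    def test_deep_tail_recurrence(self):
        # sf(k) = sf(k+1) + pmf(k) must hold in the deep tail too
        mu = 5.0
        for k in (800, 1200):
            lhs = 10.0 ** (poisson_log10_sf(k, mu) - poisson_log10_sf(k + 1, mu))
            pmf_over_sf = 10.0 ** (
                stats.poisson.logpmf(k, mu) / np.log(10) - poisson_log10_sf(k + 1, mu)
            )
            assert lhs == pytest.approx(1.0 + pmf_over_sf, rel=1e-9)

    def test_monotone_decreasing_in_k(self):
        vals = [poisson_log10_sf(k, 10.0) for k in (10, 100, 500, 1000)]
        assert vals == sorted(vals, reverse=True)

    def test_k_zero_is_certain(self):
        assert poisson_log10_sf(0, 3.0) == 0.0


class TestEstimateDensity:
    def test_integrates_to_tag_count(self):
        tags = uniform_tags(500, 100_000, seed=1)
        profile = estimate_density(tags, bandwidth=30, step=10)["chr1"]
        assert profile.values.sum() * profile.step == pytest.approx(500, rel=1e-3)

    def test_linear_in_tags(self):
        pos = np.array([5000, 5010, 5020, 7000])
        single = TagCollection({"chr1": 10_000}, {"chr1": pos})
        double = TagCollection({"chr1": 10_000}, {"chr1": np.concatenate([pos, pos])})
        d1 = estimate_density(single)["chr1"].values
        d2 = estimate_density(double)["chr1"].values
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_empty_collection_gives_zero_profile(self):
        profile = estimate_density(TagCollection({"chr1": 10_000}))["chr1"]
        assert profile.values.shape == (1000,)
        assert np.all(profile.values == 0)

    def test_uniform_tags_are_flat_when_kernel_spans_many_tags(self):
        # At 1 tag/kb a kernel must span many inter-tag gaps to look flat;
        # with bandwidth 2 kb (~2 tags per kernel SD) max/mean stays below 3.
        bandwidth, step = 2000, 10
        trim = 6 * bandwidth // step + 100  # kernel support at the zero-padded edges
        for seed in range(10):
            tags = uniform_tags(1000, 1_000_000, seed=seed)
            values = estimate_density(tags, bandwidth=bandwidth, step=step)["chr1"].values
            interior = values[trim:-trim]
            assert interior.max() / interior.mean() < 3.0

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(TagCollection({"chr1": 10_000}), bandwidth=0)


class TestCandidatePeaks:
    @staticmethod
    def _clustered_tags(centers, n_each, length=100_000, seed=0):
        rng = np.random.default_rng(seed)
        parts = [
            np.clip(rng.normal(c, 50, size=n_each).astype(np.int64), 0, length - 1)
            for c in centers
        ]
        return TagCollection({"chr1": length}, {"chr1": np.concatenate(parts)})

    def test_single_cluster_yields_one_candidate_at_summit(self):
        tags = self._clustered_tags([50_000], 500)
        profile = estimate_density(tags)["chr1"]
        cands = call_candidate_peaks(profile, min_density=0.01)
        assert len(cands) == 1
        assert abs(cands[0].summit - 50_000) <= 100
        assert cands[0].interval.start < cands[0].summit < cands[0].interval.end

    def test_two_clusters_yield_disjoint_candidates(self):
        tags = self._clustered_tags([30_000, 60_000], 500)
        profile = estimate_density(tags)["chr1"]
        cands = call_candidate_peaks(profile, min_density=0.01)
        assert len(cands) == 2
        assert cands[0].interval.end <= cands[1].interval.start

    def test_threshold_above_maximum_yields_nothing(self):
        tags = self._clustered_tags([50_000], 50)
        profile = estimate_density(tags)["chr1"]
        assert call_candidate_peaks(profile, min_density=1e6) == []

    def test_boundary_fraction_validated(self):
        profile = estimate_density(self._clustered_tags([50_000], 100))["chr1"]
        with pytest.raises(ValueError):
            call_candidate_peaks(profile, min_density=0.01, boundary_fraction=1.5)


class TestScorePeak:
    def test_hand_worked_uniform_enrichment(self):
        # 1-kb window on a 2-Mb genome with 20,000 chip tags: uniform
        # expectation is 10 tags; 300 observed tags give fold_uniform 30.
        rng = np.random.default_rng(3)
        window = GenomicInterval("chr1", 1_000_000, 1_001_000)
        inside = rng.integers(window.start, window.end, size=300, dtype=np.int64)
        outside = rng.integers(0, 900_000, size=19_700, dtype=np.int64)
        chip = TagCollection({"chr1": 2_000_000}, {"chr1": np.concatenate([inside, outside])})
        ctrl = uniform_tags(10_000, 2_000_000, seed=4)
        peak = score_peak(Peak(window, summit=1_000_500), chip, ctrl)
        assert peak.chip_count == 300
        assert peak.fold_uniform == pytest.approx(30.0)
        # 300 tags at expectation 10 is far beyond the linear-scale underflow
        # limit; the log10 p must stay finite and extreme
        assert np.isfinite(peak.log10_p) and peak.log10_p < -300

    def test_log10_p_matches_scipy_at_moderate_counts(self):
        rng = np.random.default_rng(9)
        window = GenomicInterval("chr1", 50_000, 51_000)
        inside = rng.integers(window.start, window.end, size=40, dtype=np.int64)
        outside = rng.integers(0, 40_000, size=1_960, dtype=np.int64)
        chip = TagCollection({"chr1": 100_000}, {"chr1": np.concatenate([inside, outside])})
        ctrl = uniform_tags(1000, 100_000, seed=10)
        peak = score_peak(Peak(window, summit=50_500), chip, ctrl)
        mu = 2000 * 1000 / 100_000  # uniform expectation: 20 tags
        assert peak.log10_p == pytest.approx(
            stats.poisson.logsf(peak.chip_count - 1, mu) / np.log(10), rel=1e-12
        )

    def test_fold_input_matches_count_oracle(self):
        chip = uniform_tags(5000, 100_000, seed=5)
        ctrl = uniform_tags(2000, 100_000, seed=6)
        window = GenomicInterval("chr1", 40_000, 41_000)
        peak = score_peak(Peak(window, summit=40_500), chip, ctrl, pseudocount=0.5)
        k = int(np.sum((chip.tags["chr1"] >= 40_000) & (chip.tags["chr1"] < 41_000)))
        k_in = int(np.sum((ctrl.tags["chr1"] >= 40_000) & (ctrl.tags["chr1"] < 41_000)))
        expected = (k / 5000) / ((k_in + 0.5) / 2000)
        assert peak.fold_input == pytest.approx(expected, rel=1e-12)

    def test_summit_must_lie_inside_interval(self):
        with pytest.raises(ValueError):
            Peak(GenomicInterval("chr1", 100, 200), summit=200)


class TestBHQvalues:
    def test_hand_worked_example(self):
        log10_p = np.log10([1e-20, 1e-12, 0.5])
        q = 10.0 ** bh_log10_qvalues(log10_p)
        np.testing.assert_allclose(q, [3e-20, 1.5e-12, 0.5], rtol=1e-10)

    def test_matches_statsmodels_on_random_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 50)))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            q = 10.0 ** bh_log10_qvalues(np.log10(p))
            np.testing.assert_allclose(q, q_ref, rtol=1e-9)

    def test_stays_exact_below_linear_underflow(self):
        log10_p = np.array([-500.0, -400.0, -0.5])
        log10_q = bh_log10_qvalues(log10_p)
        assert np.all(np.isfinite(log10_q))
        assert log10_q[0] == pytest.approx(-500.0 + np.log10(3.0))

    def test_q_never_exceeds_one_and_order_preserved(self):
        rng = np.random.default_rng(8)
        log10_p = np.log10(rng.uniform(0.0001, 1.0, size=100))
        log10_q = bh_log10_qvalues(log10_p)
        assert np.all(log10_q <= 0.0)
        order = np.argsort(log10_p)
        assert np.all(np.diff(log10_q[order]) >= -1e-12)

    def test_empty_input(self):
        assert bh_log10_qvalues(np.array([])).size == 0


class TestFinalizePeaks:
    @staticmethod
    def _scored(fold_input=10.0, fold_uniform=100.0, log10_p=-50.0):
        return Peak(
            GenomicInterval("chr1", 0, 100),
            summit=50,
            chip_count=100,
            fold_input=fold_input,
            fold_uniform=fold_uniform,
            log10_p=log10_p,
        )

    def test_strict_filters_reject_exact_thresholds(self):
        # single candidate: q-score == -log10_p, so each boundary is exact
        assert finalize_peaks([self._scored(fold_input=3.0)]) == []
        assert finalize_peaks([self._scored(fold_uniform=30.0)]) == []
        assert finalize_peaks([self._scored(log10_p=-10.0)]) == []

    def test_just_above_thresholds_accepted(self):
        accepted = finalize_peaks(
            [self._scored(fold_input=3.000001, fold_uniform=30.000001, log10_p=-10.000001)]
        )
        assert len(accepted) == 1
        assert accepted[0].q_score == pytest.approx(10.000001)

    def test_unscored_candidates_rejected(self):
        cand = Peak(GenomicInterval("chr1", 0, 100), summit=50)
        with pytest.raises((ValueError, TypeError)):
            finalize_peaks([cand])

    def test_output_coordinate_sorted(self):
        a = Peak(GenomicInterval("chr1", 500, 600), 550, 10, 10.0, 100.0, -50.0)
        b = Peak(GenomicInterval("chr1", 100, 200), 150, 10, 10.0, 100.0, -50.0)
        assert [p.interval.start for p in finalize_peaks([a, b])] == [100, 500]


class TestCallPeaks:
    def test_uniform_tags_yield_no_accepted_peaks(self):
        for seed in range(5):
            chip = uniform_tags(1000, 1_000_000, seed=100 + seed)
            ctrl = uniform_tags(1000, 1_000_000, seed=200 + seed)
            assert call_peaks(chip, ctrl) == []

    def test_planted_sites_are_recovered(self, small_experiment):
        _, sites, tags = small_experiment
        peaks_a = call_peaks(tags["A"], tags["input"])
        majors = [s for s in sites if s.lambda_a > 0]
        for site in majors:
            assert any(abs(p.summit - site.interval.midpoint) <= 100 for p in peaks_a)
        # no peak far from every planted site (background stays quiet)
        for p in peaks_a:
            assert min(abs(p.summit - s.interval.midpoint) for s in sites) <= 500

    def test_relaxed_qscore_threshold_accepts_superset(self, small_experiment):
        _, _, tags = small_experiment
        default = call_peaks(tags["A"], tags["input"])
        relaxed = call_peaks(tags["A"], tags["input"], min_qscore=1e-9)
        default_keys = {(p.interval.start, p.interval.end) for p in default}
        relaxed_keys = {(p.interval.start, p.interval.end) for p in relaxed}
        assert default_keys <= relaxed_keys


class TestWritePeaks:
    def test_bed_round_trip_fields(self, tmp_path):
        peak = Peak(
            GenomicInterval("chr1", 100, 400), 250, 300, 12.5, 60.0, -80.0, -78.0
        )
        path = tmp_path / "peaks.bed"
        write_peaks_bed([peak], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#chrom")
        fields = lines[1].split("\t")
        assert fields[:4] == ["chr1", "100", "400", "peak_1"]
        assert float(fields[4]) == pytest.approx(78.0)  # q-score
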