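import numpy as np
import pytest
from scipy.stats import hypergeom

import orichrom as oc


def acs(oid, start, strand="W"):
    return oc.AcsAnnotation(oid, "chrI", start, strand)


def tss(coord, chrom="chrI"):
    return oc.FeatureRecord("TSS", chrom, coord)


class TestAnnotateContext:
    def test_watson_origin_positive_distance(self):
        ann = oc.annotate_context([acs("o1", 5000)], [tss(5100)])
        assert ann[0].distances["TSS"] == 100

    def test_crick_origin_reflects_distance(self):
        ann = oc.annotate_context([acs("o1", 5000, "C")], [tss(5100)])
        assert ann[0].distances["TSS"] == -100

    def test_nearest_feature_chosen(self):
        ann = oc.annotate_context([acs("o1", 5000)], [tss(4000), tss(5200)])
        assert ann[0].distances["TSS"] == 200

    def test_missing_feature_is_none(self):
        ann = oc.annotate_context(
            [acs("o1", 5000)], [tss(100, chrom="chrII")]
        )
        assert ann[0].distances["TSS"] is None


class TestMovingSum:
    def test_single_feature_peak_at_offset(self):
        res = oc.moving_sum_distribution([112])
        assert res.total == 1
        assert res.positions[np.argmax(res.smoothed)] == pytest.approx(112, abs=8)

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        offsets = 4 * rng.integers(-150, 151, size=150)  # interior of the grid
        res = oc.moving_sum_distribution(offsets)
        assert res.total == 150
        # interior offsets contribute to exactly window_probes windows
        assert res.moving_sum.sum() == 150 * res.window_probes

    def test_out_of_range_offsets_dropped(self):
        res = oc.moving_sum_distribution([0, 5000])
        assert res.total == 1

    def test_three_planted_peaks_recovered(self):
        offsets = [-276] * 40 + [112] * 50 + [328] * 45
        res = oc.moving_sum_distribution(offsets)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(res.smoothed, distance=20)
        found = sorted(res.positions[peaks[np.argsort(res.smoothed[peaks])[-3:]]])
        for want, got in zip([-276, 112, 328], found):
            assert abs(want - got) <= 8


class TestWindowedTiming:
    def build(self, n, early, offset=0):
        offsets = {f"o{i}": [offset] for i in range(n)}
        timing = {
            f"o{i}": oc.TimingRecord(f"o{i}", early=bool(early[i]), trep=20.0 + i)
            for i in range(n)
        }
        return offsets, timing

    def test_window_with_four_origins_is_masked(self):
        offsets, timing = self.build(4, [1, 1, 1, 1])
        stats = oc.windowed_timing(offsets, timing)
        at0 = next(s for s in stats if s.center == 0)
        assert at0.n_origins == 4 and at0.masked

    def test_window_with_five_early_origins(self):
        offsets, timing = self.build(5, [1, 1, 1, 1, 1])
        stats = oc.windowed_timing(offsets, timing)
        at0 = next(s for s in stats if s.center == 0)
        assert not at0.masked and at0.value == 1.0

    def test_mean_trep_over_present_values(self):
        offsets, timing = self.build(5, [1, 0, 1, 0, 1])
        timing["o3"] = oc.TimingRecord("o3", early=False, trep=None)
        stats = oc.windowed_timing(offsets, timing, statistic="mean_trep")
        at0 = next(s for s in stats if s.center == 0)
        expected = np.mean([20.0, 21.0, 22.0, 24.0])
        assert at0.value == pytest.approx(expected)

    def test_origin_missing_timing_excluded_with_warning(self):
        offsets, timing = self.build(5, [1] * 5)
        del timing["o4"]
        with pytest.warns(UserWarning, match="missing timing"):
            stats = oc.windowed_timing(offsets, timing)
        at0 = next(s for s in stats if s.center == 0)
        assert at0.n_origins == 4


class TestAssignTrep:
    def test_nearest_point(self):
        assert oc.assign_trep(1000, [900, 1200], [20.0, 40.0]) == 20.0

    def test_tie_takes_lower_coordinate(self):
        assert oc.assign_trep(1000, [900, 1100], [20.0, 40.0]) == 20.0

    def test_single_point(self):
        assert oc.assign_trep(1000, [5], [33.0]) == 33.0

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            oc.assign_trep(1000, [], [])


class TestResampleProportion:
    def test_full_set_subset_is_zero(self):
        labels = np.array([True] * 8 + [False] * 12)
        pct = oc.resample_proportion_test(labels, np.arange(20), seed=1)
        assert pct == 0.0

    def test_matches_hypergeometric_tail(self):
        # 20 origins, 8 early; subset of 10 containing 7 early
        labels = np.array([True] * 8 + [False] * 12)
        subset = np.array([0, 1, 2, 3, 4, 5, 6, 8, 9, 10])
        reps = 10000
        pct = oc.resample_proportion_test(labels, subset, reps=reps, seed=42)
        exact = 100 * hypergeom.cdf(6, 20, 8, 10)
        p = exact / 100
        se = 100 * np.sqrt(p * (1 - p) / reps)
        assert abs(pct - exact) < 3 * se

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        labels = rng.random(100) < 0.4
        subset = rng.choice(100, 30, replace=False)
        a = oc.resample_proportion_test(labels, subset, seed=7)
        b = oc.resample_proportion_test(labels, subset, seed=7)
        assert a == b

    def test_oversized_subset_errors(self):
        with pytest.raises(ValueError):
            oc.resample_proportion_test(np.array([True, False]), np.arange(3))


class TestNdrQuantileTiming:
    def timing_map(self, labels):
        return {
            f"o{i}": oc.TimingRecord(f"o{i}", early=bool(v))
            for i, v in enumerate(labels)
        }

    def test_equal_widths_error(self):
        widths = {f"o{i}": 200 for i in range(20)}
        timing = self.timing_map([1] * 20)
        with pytest.raises(ValueError, match="degenerate"):
            oc.ndr_quantile_timing(widths, timing)

    def test_bin_sizes_differ_by_at_most_one(self):
        widths = {f"o{i}": 160 + 4 * i for i in range(40)}
        timing = self.timing_map([i % 2 for i in range(40)])
        bins = oc.ndr_quantile_timing(widths, timing, reps=200, seed=0)
        sizes = [len(b.origin_ids) for b in bins]
        assert len(bins) == 7
        assert sum(sizes) == 40 and max(sizes) - min(sizes) <= 1

    def test_planted_late_extremes_score_low(self):
        n = 70
        widths = {f"o{i}": 160 + 8 * i for i in range(n)}
        labels = []
        for i in range(n):
            labels.append(0 if (i < 10 or i >= n - 10) else (i % 10 < 7))
        timing = self.timing_map(labels)
        bins = oc.ndr_quantile_timing(widths, timing, reps=4000, seed=5)
        assert bins[0].early_proportion == 0.0
        assert bins[-1].early_proportion == 0.0
        assert bins[0].percentile < 5 and bins[-1].percentile < 5
        assert max(b.percentile for b in bins[1:-1]) > 50

    def test_null_labels_spread_across_percentiles(self):
        rng = np.random.default_rng(11)
        n = 140
        widths = {f"o{i}": 160 + 4 * i for i in range(n)}
        timing = self.timing_map(rng.random(n) < 0.4)
        bins = oc.ndr_quantile_timing(widths, timing, reps=2000, seed=11)
        pcts = [b.percentile for b in bins]
        assert 20 < np.mean(pcts) < 80

    def test_too_many_quantiles_errors(self):
        widths = {f"o{i}": 160 + 4 * i for i in range(5)}
        timing = self.timing_map([1] * 5)
        with pytest.raises(ValueError):
            oc.ndr_quantile_timing(widths, timing, n_quantiles=7)
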