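import numpy as np
import pytest

from calmaug import (
    ClassDistribution,
    build_report,
    center_histogram,
    compare,
    effective_coverage,
    effective_sample_proportion,
    imbalance_ratio,
    log_dispersion,
    scale_histogram,
)

from conftest import make_dataset


def dist(counts):
    counts = list(counts)
    return ClassDistribution(np.array(counts), [f"c{i}" for i in range(len(counts))])


class TestImbalanceRatio:
    def test_plantdoc_like_extremes(self):
        # long-tail with 2..755 instances per class
        d = dist([755, 300, 120, 40, 2])
        assert imbalance_ratio(d) == pytest.approx(377.5)

    def test_post_augmentation_extremes(self):
        d = dist([5101, 900, 400, 54])
        assert imbalance_ratio(d) == pytest.approx(94.5, abs=0.05)

    def test_uniform_counts_give_one(self):
        assert imbalance_ratio(dist([7, 7, 7])) == 1.0

    def test_zero_count_classes_are_excluded(self):
        assert imbalance_ratio(dist([10, 0, 5])) == 2.0
        with pytest.raises(ValueError):
            imbalance_ratio(dist([0, 0]))


class TestLogDispersion:
    def test_uniform_counts_give_zero(self):
        assert log_dispersion(dist([42, 42, 42])) == 0.0

    def test_two_class_value_is_half_log_gap(self):
        # population SD of {ln 10, ln 1000} is half their gap = ln 10
        assert log_dispersion(dist([10, 1000])) == pytest.approx(
            np.log(10), abs=1e-12
        )

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(1, 10_000, size=rng.integers(2, 40))
            base = log_dispersion(dist(counts))
            for factor in (2, 10, 137):
                assert log_dispersion(dist(counts * factor)) == pytest.approx(
                    base, abs=1e-9
                )

    def test_configurable_base(self):
        assert log_dispersion(dist([10, 1000]), base=10) == pytest.approx(1.0)

    def test_needs_two_positive_classes(self):
        with pytest.raises(ValueError):
            log_dispersion(dist([5, 0, 0]))


class TestEffectiveCoverage:
    def test_seventeen_of_thirty_qualify(self):
        counts = [200] * 17 + [199] * 13
        count, frac = effective_coverage(dist(counts), 200)
        assert count == 17 and frac == pytest.approx(17 / 30, abs=5e-4)

    def test_twentynine_of_thirty_qualify(self):
        counts = [250] * 29 + [54]
        count, frac = effective_coverage(dist(counts), 200)
        assert count == 29 and frac == pytest.approx(29 / 30, abs=5e-4)

    def test_zero_threshold_covers_everything(self):
        assert effective_coverage(dist([3, 0, 9]), 0) == (3, 1.0)

    def test_fraction_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = dist(rng.integers(0, 500, size=25))
            fracs = [effective_coverage(d, n0)[1] for n0 in range(0, 600, 25)]
            assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestEffectiveSampleProportion:
    def test_all_classes_effective(self):
        assert effective_sample_proportion(dist([100, 300]), 50) == 1.0

    def test_partial(self):
        assert effective_sample_proportion(dist([100, 10]), 50) == pytest.approx(
            100 / 110
        )

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = dist(rng.integers(1, 400, size=20))
            vals = [
                effective_sample_proportion(d, n0) for n0 in range(0, 500, 20)
            ]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_distribution_raises(self):
        with pytest.raises(ValueError):
            effective_sample_proportion(dist([0, 0]), 10)


class TestHistograms:
    def test_central_boxes_fall_in_one_cell(self):
        ds = make_dataset([[(0, 0.5, 0.5, 0.2, 0.1)] * 3])
        grid = center_histogram(ds, bins=2)
        # interior-edge values go to the upper bin
        assert grid[1, 1] == 1.0 and grid.sum() == pytest.approx(1.0)

    def test_single_box_single_cell(self):
        grid = center_histogram(make_dataset([[(0, 0.1, 0.9, 0.1, 0.1)]]), bins=4)
        assert grid[3, 0] == 1.0 and np.count_nonzero(grid) == 1

    def test_uniform_centers_pass_multinomial_bound(self):
        rng = np.random.default_rng(17)
        n, bins = 10_000, 4
        boxes = [
            (0, rng.uniform(0.0005, 0.9995), rng.uniform(0.0005, 0.9995), 0.001, 0.001)
            for _ in range(n)
        ]
        grid = center_histogram(make_dataset([boxes]), bins=bins)
        p = 1 / bins**2
        bound = 3 * np.sqrt(p * (1 - p) / n)
        assert np.max(np.abs(grid - p)) < bound

    def test_zero_boxes_gives_sentinel(self):
        ds = make_dataset([[]], num_classes=1)
        assert center_histogram(ds, 3).sum() == 0.0
        assert scale_histogram(ds, 3).sum() == 0.0

    def test_scale_histogram_matches_independent_binning(self):
        rng = np.random.default_rng(23)
        boxes = []
        for _ in range(500):
            w, h = rng.uniform(0.02, 0.9, size=2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            boxes.append((0, cx, cy, w, h))
        bins = 10
        grid = scale_histogram(make_dataset([boxes]), bins=bins)
        expected = np.zeros(bins)
        for _, cx, cy, w, h in boxes:  # brute-force binning oracle
            expected[min(bins - 1, int(np.sqrt(w * h) * bins))] += 1
        assert np.allclose(grid, expected / expected.sum())

    def test_same_size_boxes_occupy_one_bin(self):
        ds = make_dataset([[(0, 0.5, 0.5, 0.25, 0.25)] * 4])
        assert np.count_nonzero(scale_histogram(ds, 10)) == 1


class TestCompare:
    def _report(self, counts, **over):
        boxes = [
            [(cid, 0.5, 0.5, 0.1, 0.1)] * n for cid, n in enumerate(counts)
        ]
        return build_report(make_dataset(boxes, num_classes=len(counts)), n0=200)

    def test_identical_reports_give_zero_deltas(self):
        r = self._report([300, 250, 10])
        delta = compare(r, r)
        assert delta.imbalance_ratio_delta == 0.0
        assert delta.effective_count_delta == 0
        assert not delta.ir_decreased and not delta.coverage_increased

    def test_headline_ir_change_is_flagged(self):
        before = self._report([755, 300, 2])
        after = self._report([5101, 2000, 54])
        delta = compare(before, after)
        assert delta.imbalance_ratio_delta == pytest.approx(
            5101 / 54 - 377.5, abs=0.05
        )
        assert delta.ir_decreased

    def test_coverage_gain_counts_classes(self):
        before = self._report([300] * 17 + [100] * 13)
        after = self._report([300] * 29 + [54])
        assert compare(before, after).effective_count_delta == 12

    def test_mismatched_class_tables_raise(self):
        with pytest.raises(ValueError):
            compare(self._report([10, 10]), self._report([10, 10, 10]))
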