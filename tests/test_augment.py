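import numpy as np
import pytest

from calmaug import (
    AugPolicy,
    ClassDistribution,
    DetectionDataset,
    build_bank,
    class_deficits,
    effective_coverage,
    extract_instances,
    imbalance_ratio,
    paste,
    plan_and_augment,
)
from calmaug.augment import PlacementError, sample_placement
from calmaug.lesion_bank import EmptyClassError, LesionInstance

from conftest import make_dataset


def dist(counts):
    return ClassDistribution(np.array(counts), [f"c{i}" for i in range(len(counts))])


class TestClassDeficits:
    def test_tail_class_deficit_to_floor(self):
        assert list(class_deficits(dist([755, 2]), 54)) == [0, 52]

    def test_no_deficit_when_all_above_target(self):
        assert list(class_deficits(dist([60, 70]), 54)) == [0, 0]

    def test_per_class_target_vector(self):
        assert list(class_deficits(dist([10, 10]), [5, 25])) == [0, 15]

    def test_non_positive_targets_raise(self):
        with pytest.raises(ValueError):
            class_deficits(dist([1, 2]), 0)


class TestSamplePlacement:
    def test_empty_frame_placements_are_uniform_to_the_edges(self):
        rng = np.random.default_rng(37)
        n, bins = 10_000, 4
        w = h = 0.05
        draws = np.array(
            [
                sample_placement((128, 128), (w, h), [], 0.0, rng)
                for _ in range(n)
            ]
        )
        # normalize the feasible center range [w/2, 1-w/2] back to [0,1)
        norm = (draws - w / 2) / (1 - w)
        grid, _, _ = np.histogram2d(
            norm[:, 0], norm[:, 1], bins=bins, range=[[0, 1], [0, 1]]
        )
        p = 1 / bins**2
        assert np.max(np.abs(grid / n - p)) < 3 * np.sqrt(p * (1 - p) / n)

    def test_frame_filling_box_has_unique_center(self):
        rng = np.random.default_rng(0)
        assert sample_placement((64, 64), (1.0, 1.0), [], 0.0, rng) == (0.5, 0.5)

    def test_tiled_frame_is_infeasible(self):
        existing = [
            (x + 0.125, y + 0.125, 0.25, 0.25)
            for x in np.arange(0, 1, 0.25)
            for y in np.arange(0, 1, 0.25)
        ]
        with pytest.raises(PlacementError):
            sample_placement(
                (64, 64), (0.25, 0.25), existing, 0.0, np.random.default_rng(1)
            )


def hard_instance(size=20, class_id=0, frame=128, value=200):
    pixels = np.full((size, size, 3), value, dtype=np.uint8)
    return LesionInstance(
        pixels, np.ones((size, size)), class_id, ("donor", 0), size / frame
    )


class TestPaste:
    def test_hard_paste_changes_exactly_the_crop_rectangle(self):
        bg = np.zeros((128, 128, 3), dtype=np.uint8)
        inst = hard_instance(20)
        sample = paste(bg, [], inst, (0.5, 0.5), 1.0, blend_mode="hard")
        diff = np.any(sample.image != bg, axis=-1)
        assert diff.sum() == 400
        ann = sample.annotations[-1]
        assert ann.w * 128 == pytest.approx(20, abs=1)
        assert ann.cx == pytest.approx(0.5, abs=1 / 128)
        # background outside the rectangle is bit-identical
        ys, xs = np.nonzero(diff)
        assert xs.max() - xs.min() + 1 == 20 and ys.max() - ys.min() + 1 == 20

    def test_feathered_interior_equals_donor(self):
        bg = np.zeros((128, 128, 3), dtype=np.uint8)
        size = 24
        alpha = np.zeros((size, size))
        alpha[4:-4, 4:-4] = 1.0
        inst = LesionInstance(
            np.full((size, size, 3), 180, np.uint8), alpha, 0, ("d", 0), size / 128
        )
        sample = paste(bg, [], inst, (0.5, 0.5), 1.0, blend_mode="feathered")
        interior = sample.image[60:68, 60:68]
        assert np.all(interior == 180)

    def test_annotation_count_increases_by_one_and_originals_unchanged(self):
        ds = make_dataset([[(1, 0.2, 0.2, 0.1, 0.1)]], image_size=128)
        item = ds.items[0]
        sample = paste(
            item.image, item.annotations, hard_instance(16), (0.7, 0.7), 1.0, "hard"
        )
        assert len(sample.annotations) == 2
        assert sample.annotations[0] == item.annotations[0]
        assert sample.n_original == 1
        assert len(sample.provenance) == 1

    def test_out_of_frame_paste_raises(self):
        bg = np.zeros((64, 64, 3), dtype=np.uint8)
        with pytest.raises(PlacementError):
            paste(bg, [], hard_instance(20, frame=64), (0.02, 0.5), 1.0, "hard")


class TestPlanAndAugment:
    def _setup(self, fixture):
        ds = fixture.dataset
        bank = build_bank(extract_instances(ds, 0.05, masks=fixture.masks))
        return ds, bank

    def test_scheduled_pastes_equal_total_deficit(self, small_fixture):
        ds, bank = self._setup(small_fixture)
        policy = AugPolicy(target_count=8, scale_jitter=(0.8, 1.2))
        rng = np.random.default_rng(4)
        samples, planned = plan_and_augment(ds, bank, policy, None, rng)
        deficits = class_deficits(ClassDistribution.from_dataset(ds), 8)
        pasted = sum(len(s.annotations) - s.n_original for s in samples)
        assert pasted == deficits.sum() == 9  # (0, 0, 3, 6)
        assert all(s.pending_screen for s in samples)
        assert all(len(s.provenance) == len(s.annotations) - s.n_original for s in samples)

    def test_planned_counts_reach_floor_and_ir_drops(self, small_fixture):
        ds, bank = self._setup(small_fixture)
        before = ClassDistribution.from_dataset(ds)
        policy = AugPolicy(target_count=8, scale_jitter=(0.8, 1.2))
        _, planned = plan_and_augment(ds, bank, policy, None, np.random.default_rng(4))
        assert planned.counts.min() >= 8
        assert imbalance_ratio(planned) < imbalance_ratio(before)
        assert np.all(planned.counts >= before.counts)

    def test_no_deficit_emits_nothing(self, small_fixture):
        ds, bank = self._setup(small_fixture)
        samples, planned = plan_and_augment(
            ds, bank, AugPolicy(target_count=1), None, np.random.default_rng(0)
        )
        assert samples == []
        assert list(planned.counts) == [14, 9, 5, 2]

    def test_emitted_boxes_respect_overlap_ceiling_and_invariants(self, small_fixture):
        from calmaug import iou

        ds, bank = self._setup(small_fixture)
        policy = AugPolicy(target_count=8, scale_jitter=(0.8, 1.2), max_overlap_iou=0.1)
        samples, _ = plan_and_augment(ds, bank, policy, None, np.random.default_rng(8))
        for s in samples:
            originals = [a.box for a in s.annotations[: s.n_original]]
            for pasted in s.annotations[s.n_original :]:
                assert 0 < pasted.w <= 1 and 0 < pasted.h <= 1
                for b in originals:
                    assert iou(pasted.box, b) <= 0.1 + 0.05  # mask-derived box slack

    def test_reproducible_under_seed(self, small_fixture):
        ds, bank = self._setup(small_fixture)
        policy = AugPolicy(target_count=6, scale_jitter=(0.8, 1.2))
        a, _ = plan_and_augment(ds, bank, policy, None, np.random.default_rng(21))
        b, _ = plan_and_augment(ds, bank, policy, None, np.random.default_rng(21))
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image, sb.image)
            assert sa.annotations == sb.annotations

    def test_coverage_dominance_after_augmentation(self, small_fixture):
        ds, bank = self._setup(small_fixture)
        policy = AugPolicy(target_count=8, scale_jitter=(0.8, 1.2))
        samples, _ = plan_and_augment(ds, bank, policy, None, np.random.default_rng(2))
        counts = ClassDistribution.from_dataset(ds).counts.copy()
        for s in samples:
            for ann in s.annotations[s.n_original :]:
                counts[ann.class_id] += 1
        after = ClassDistribution(counts, ds.class_names)
        before = ClassDistribution.from_dataset(ds)
        for n0 in range(0, 9):
            assert (
                effective_coverage(after, n0)[0] >= effective_coverage(before, n0)[0]
            )

    def test_deficit_class_with_empty_bank_raises(self, small_fixture):
        ds, _ = self._setup(small_fixture)
        bank = build_bank([])
        with pytest.raises(EmptyClassError):
            plan_and_augment(
                ds, bank, AugPolicy(target_count=8), None, np.random.default_rng(0)
            )
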