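"""Metric-layer tests: Dice, average Hausdorff distance, subvolume
partition, aggregation, and the paired one-tailed t-test — each checked
against an independent oracle (brute-force all-pairs distances, direct
arithmetic, scipy's reference test)."""

import math

import numpy as np
import pytest
from scipy import stats

from segtemplate.evalmetrics import (
    MetricRecord,
    aggregate,
    average_hausdorff,
    evaluate_case,
    paired_onetailed_test,
    regional_dice,
    soft_dice,
    split_subvolumes,
)
from segtemplate.imgio import AxisConvention, SegmentationMask

from conftest import random_binary_mask


def mask_from_points(points, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    data = np.zeros(shape, dtype=np.float32)
    for p in points:
        data[tuple(p)] = 1.0
    return SegmentationMask(data, spacing)


def brute_force_ahd(pred: SegmentationMask, ref: SegmentationMask):
    """Exhaustive all-pairs oracle for the average Hausdorff distance."""
    sp = np.asarray(ref.spacing_mm)
    X = np.argwhere(ref.data > 0.5) * sp
    Y = np.argwhere(pred.data > 0.5) * sp
    if len(X) == 0 or len(Y) == 0:
        return None
    d = np.sqrt(((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
    return (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2.0


class TestSoftDice:
    def test_perfect_overlap(self, rng):
        m = random_binary_mask(rng, (6, 6, 6))
        assert soft_dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = mask_from_points([(0, 0, 0), (1, 0, 0)])
        b = mask_from_points([(5, 5, 5), (6, 5, 5)])
        assert soft_dice(a, b) == 0.0

    def test_single_shared_voxel(self):
        a = mask_from_points([(0, 0, 0), (1, 0, 0)])
        b = mask_from_points([(0, 0, 0), (2, 2, 2)])
        assert soft_dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        e = mask_from_points([])
        assert soft_dice(e, e) == 1.0

    def test_symmetry_and_range(self, rng):
        for _ in range(10):
            a = random_binary_mask(rng, (7, 7, 7))
            b = random_binary_mask(rng, (7, 7, 7))
            d = soft_dice(a, b)
            assert d == pytest.approx(soft_dice(b, a))
            assert 0.0 <= d <= 1.0

    def test_grid_mismatch_rejected(self, rng):
        a = random_binary_mask(rng, (6, 6, 6))
        b = random_binary_mask(rng, (6, 6, 7))
        with pytest.raises(ValueError, match="grid"):
            soft_dice(a, b)


class TestAverageHausdorff:
    def test_identical_masks_zero(self, rng):
        m = random_binary_mask(rng, (6, 6, 6))
        assert average_hausdorff(m, m) == 0.0

    def test_two_points_distance_three(self):
        ref = mask_from_points([(0, 0, 0)])
        pred = mask_from_points([(0, 0, 3)])
        assert average_hausdorff(pred, ref) == pytest.approx(3.0)

    def test_asymmetric_sets_hand_value(self):
        # X={(0,0,0),(0,0,2)}, Y={(0,0,1)} -> ((1+1)/2 + 1)/2 = 1.0
        ref = mask_from_points([(0, 0, 0), (0, 0, 2)])
        pred = mask_from_points([(0, 0, 1)])
        assert average_hausdorff(pred, ref) == pytest.approx(1.0)

    def test_empty_mask_undefined(self, rng):
        m = random_binary_mask(rng, (6, 6, 6))
        empty = mask_from_points([], shape=(6, 6, 6))
        assert average_hausdorff(empty, m) is None
        assert average_hausdorff(m, empty) is None

    def test_matches_brute_force_oracle(self, rng):
        """KD-tree implementation vs exhaustive all-pairs on 50 random pairs."""
        for i in range(50):
            shape = tuple(rng.integers(4, 13, size=3))
            spacing = tuple(rng.uniform(0.5, 2.0, size=3))
            a = random_binary_mask(rng, shape, p=0.2, spacing=spacing)
            b = random_binary_mask(rng, shape, p=0.2, spacing=spacing)
            got = average_hausdorff(a, b)
            want = brute_force_ahd(a, b)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_anisotropic_spacing_in_mm(self):
        ref = mask_from_points([(0, 0, 0)], spacing=(1.0, 1.0, 2.5))
        pred = mask_from_points([(0, 0, 1)], spacing=(1.0, 1.0, 2.5))
        assert average_hausdorff(pred, ref) == pytest.approx(2.5)


class TestSubvolumePartition:
    def _mask_with_slices(self, n_fg, n_total=60, offset=3):
        data = np.zeros((4, 4, n_total), dtype=np.float32)
        data[1:3, 1:3, offset : offset + n_fg] = 1.0
        return SegmentationMask(data, (1, 1, 1))

    def test_eight_slices_exact_quarters(self):
        part = split_subvolumes(self._mask_with_slices(8))
        assert len(part.apex_slices) == 2
        assert len(part.mid_slices) == 4
        assert len(part.base_slices) == 2

    def test_ten_slices_rounds_half_away(self):
        part = split_subvolumes(self._mask_with_slices(10))
        assert len(part.apex_slices) == 3
        assert len(part.base_slices) == 3
        assert len(part.mid_slices) == 4

    def test_single_slice_goes_to_mid(self):
        part = split_subvolumes(self._mask_with_slices(1))
        assert len(part.apex_slices) == 0
        assert len(part.base_slices) == 0
        assert len(part.mid_slices) == 1

    @pytest.mark.parametrize("n", list(range(1, 51)))
    def test_conservation_and_sizing(self, n):
        """apex+mid+base partition the n foreground slices, 25/50/25 sized."""
        part = split_subvolumes(self._mask_with_slices(n, n_total=n + 6))
        quarter = int(math.floor(0.25 * n + 0.5))
        assert len(part.apex_slices) == quarter
        assert len(part.base_slices) == quarter
        all_slices = set(part.apex_slices) | set(part.mid_slices) | set(part.base_slices)
        assert len(all_slices) == n
        assert not set(part.apex_slices) & set(part.base_slices)

    def test_apex_end_follows_axis_convention(self):
        m = self._mask_with_slices(8)
        low = split_subvolumes(m, AxisConvention(apex_low=True))
        high = split_subvolumes(m, AxisConvention(apex_low=False))
        assert min(low.apex_slices) < min(low.base_slices)
        assert min(high.apex_slices) > min(high.base_slices)

    def test_empty_reference_rejected(self):
        empty = SegmentationMask(np.zeros((4, 4, 4), dtype=np.float32), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            split_subvolumes(empty)


class TestRegionalDice:
    def test_perfect_prediction_all_ones(self, rng):
        ref = self_ref = random_binary_mask(rng, (6, 6, 9), p=0.4)
        overall, base, mid, apex = regional_dice(ref, ref)
        assert (overall, base, mid, apex) == (1.0, 1.0, 1.0, 1.0)

    def test_region_independence(self):
        data = np.zeros((4, 4, 8), dtype=np.float32)
        data[1:3, 1:3, :] = 1.0  # 8 foreground slices -> 2/4/2
        ref = SegmentationMask(data, (1, 1, 1))
        part = split_subvolumes(ref)
        pred_data = np.zeros_like(data)
        for s in part.mid_slices:
            pred_data[:, :, s] = data[:, :, s]
        pred = SegmentationMask(pred_data, (1, 1, 1))
        overall, base, mid, apex = regional_dice(pred, ref, part)
        assert mid == 1.0
        assert apex == 0.0 and base == 0.0
        assert overall == pytest.approx(soft_dice(pred, ref))


class TestAggregate:
    def _rec(self, cid, dice, ahd=0.1, fold=0):
        return MetricRecord(cid, dice, dice, dice, dice, ahd, fold, "m")

    def test_hand_mean_and_sd(self):
        agg = aggregate([self._rec("a", 0.8), self._rec("b", 0.9)])
        assert agg["dice_overall"]["mean"] == pytest.approx(0.85)
        assert agg["dice_overall"]["sd"] == pytest.approx(0.0707, abs=1e-4)

    def test_single_record_sd_missing(self):
        agg = aggregate([self._rec("a", 0.8)])
        assert agg["dice_overall"]["mean"] == pytest.approx(0.8)
        assert agg["dice_overall"]["sd"] is None

    def test_missing_ahd_excluded_and_counted(self):
        recs = [self._rec("a", 0.8), self._rec("b", 0.9, ahd=None)]
        agg = aggregate(recs)
        assert agg["ahd_mm"]["n"] == 1
        assert agg["ahd_missing"] == 1

    def test_pooling_is_image_level_not_fold_means(self, rng):
        """Pooled mean equals the direct mean over all cases, not the mean
        of per-fold means (folds here have unequal sizes)."""
        recs = [self._rec(f"c{i}", float(d), fold=0) for i, d in
                enumerate(rng.uniform(0.5, 1.0, 7))]
        recs += [self._rec(f"d{i}", float(d), fold=1) for i, d in
                 enumerate(rng.uniform(0.5, 1.0, 2))]
        agg = aggregate(recs)
        direct = np.mean([r.dice_overall for r in recs])
        fold_of_means = np.mean([
            np.mean([r.dice_overall for r in recs if r.fold == f]) for f in (0, 1)
        ])
        assert agg["dice_overall"]["mean"] == pytest.approx(direct)
        assert abs(direct - fold_of_means) > 1e-6  # the two schemes genuinely differ


class TestPairedOneTailedTest:
    def test_worked_example_against_t_oracle(self):
        """Differences [1..5]: t = 3/(1.5811/sqrt(5)) ~ 4.2426, df=4."""
        b = np.zeros(5)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_onetailed_test(a, b)
        assert res.t == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(float(stats.t.sf(res.t, 4)), rel=1e-9)
        assert res.p == pytest.approx(0.0066, abs=5e-4)

    def test_matches_scipy_reference(self, rng):
        for _ in range(5):
            a = rng.normal(0.1, 1.0, 30)
            b = rng.normal(0.0, 1.0, 30)
            res = paired_onetailed_test(a, b)
            ref = stats.ttest_rel(a, b, alternative="greater")
            assert res.t == pytest.approx(float(ref.statistic), rel=1e-9)
            assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_equal_scores_degenerate(self):
        a = np.array([0.5, 0.6, 0.7])
        res = paired_onetailed_test(a, a)
        assert res.degenerate
        assert res.p is None and not res.superior

    def test_clear_superiority_detected(self, rng):
        b = rng.normal(0.7, 0.05, 200)
        a = b + rng.uniform(0.01, 0.05, 200)
        assert paired_onetailed_test(a, b).superior

    def test_null_calibration(self, rng):
        """Under the paired-Gaussian null the rejection rate at alpha=0.001
        stays below 0.005 (10,000 simulated datasets)."""
        rejections = 0
        n_sim = 10_000
        a = rng.normal(size=(n_sim, 10))
        b = rng.normal(size=(n_sim, 10))
        d = a - b
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(10))
        p = stats.t.sf(t, 9)
        rejections = int((p < 0.001).sum())
        assert rejections / n_sim <= 0.005

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_onetailed_test([1.0, 2.0], [1.0])


class TestEvaluateCase:
    def test_full_record_perfect_prediction(self, phantom_case):
        rec = evaluate_case("c", phantom_case.truth_mask, phantom_case.truth_mask)
        assert rec.dice_overall == 1.0
        assert rec.ahd_mm == 0.0

    def test_empty_prediction_dice_zero_ahd_missing(self, phantom_case):
        empty = SegmentationMask(
            np.zeros_like(phantom_case.truth_mask.data), phantom_case.truth_mask.spacing_mm
        )
        rec = evaluate_case("c", empty, phantom_case.truth_mask)
        assert rec.dice_overall == 0.0
        assert rec.ahd_mm is None
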