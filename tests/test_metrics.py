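"""Metric definitions checked against exhaustive hand computations."""

import numpy as np
import pandas as pd
import pytest

from sarc_unet.metrics import (
    area_profile,
    centroid_drift_stats,
    dice_2d,
    dice_3d,
    dice_loss_2d,
    hausdorff_slice,
    metrics_by_offset,
    sensitivity_slice,
    specificity_slice,
    slice_metrics_table,
)
from sarc_unet.preprocess import GtvMask


def mask_from_points(points, shape=(8, 8)):
    m = np.zeros(shape, dtype=np.uint8)
    for y, x in points:
        m[y, x] = 1
    return m


class TestDice:
    def test_identical_nonempty(self):
        m = mask_from_points([(1, 1), (2, 2), (3, 3)])
        assert dice_2d(m, m) == 1.0

    def test_disjoint(self):
        assert dice_2d(mask_from_points([(0, 0)]), mask_from_points([(5, 5)])) == 0.0

    def test_partial_overlap(self):
        p = mask_from_points([(0, 0), (0, 1), (1, 0), (1, 1)])
        t = mask_from_points([(1, 0), (1, 1), (2, 0), (2, 1)])
        assert dice_2d(p, t) == pytest.approx(0.5)  # 2*2/(4+4)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dice_2d(z, z) == 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = (rng.random((6, 6)) > 0.5).astype(np.uint8)
            b = (rng.random((6, 6)) > 0.5).astype(np.uint8)
            d = dice_2d(a, b)
            assert d == dice_2d(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_2d(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.stack([mask_from_points([(1, 1), (2, 2)]), mask_from_points([(3, 3)])]).astype(np.float32)
        assert float(dice_loss_2d(t, t).data) == pytest.approx(0.0, abs=1e-5)

    def test_inverted_prediction_near_one(self):
        t = np.stack([mask_from_points([(1, 1)]), mask_from_points([(2, 2)])]).astype(np.float32)
        assert float(dice_loss_2d(1.0 - t, t).data) == pytest.approx(1.0, abs=1e-4)

    def test_equal_slice_weighting(self):
        # slice dices 1.0 and 0.5 -> loss 0.25 regardless of slice areas
        t0 = np.zeros((4, 4), dtype=np.float32)
        t0[:2, :2] = 1.0  # slice 0 predicted perfectly
        t1 = np.zeros((4, 4), dtype=np.float32)
        t1[0, :2] = 1.0
        p1 = np.zeros((4, 4), dtype=np.float32)
        p1[0, 0] = 1.0
        p1[3, 3] = 1.0  # overlap 1, |P|=2, |T|=2 -> dice 0.5
        loss = dice_loss_2d(np.stack([t0, p1]), np.stack([t0, t1]))
        assert float(loss.data) == pytest.approx(0.25, abs=1e-5)

    def test_volume_loss_equals_mean_of_per_slice_losses(self):
        rng = np.random.default_rng(1)
        pred = rng.random((5, 6, 6)).astype(np.float32)
        truth = (rng.random((5, 6, 6)) > 0.6).astype(np.float32)
        whole = float(dice_loss_2d(pred, truth).data)
        per_slice = [float(dice_loss_2d(pred[i : i + 1], truth[i : i + 1]).data) for i in range(5)]
        assert whole == pytest.approx(np.mean(per_slice), abs=1e-6)

    def test_padded_slices_excluded(self):
        rng = np.random.default_rng(2)
        pred = rng.random((4, 5, 5)).astype(np.float32)
        truth = (rng.random((4, 5, 5)) > 0.5).astype(np.float32)
        valid = np.array([True, True, False, False])
        expect = np.mean(
            [float(dice_loss_2d(pred[i : i + 1], truth[i : i + 1]).data) for i in range(2)]
        )
        assert float(dice_loss_2d(pred, truth, valid).data) == pytest.approx(expect, abs=1e-6)

    def test_no_valid_slices_errors(self):
        with pytest.raises(ValueError):
            dice_loss_2d(np.zeros((2, 3, 3)), np.zeros((2, 3, 3)), np.zeros(2, dtype=bool))


class TestDice3d:
    def test_identical(self):
        v = (np.random.default_rng(0).random((4, 5, 5)) > 0.5).astype(np.uint8)
        assert dice_3d(v, v) == 1.0

    def test_both_empty(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        assert dice_3d(z, z) == 1.0

    def test_volume_dice_weighted_toward_large_slices(self):
        # slice 0: 9 voxels, predicted perfectly; slice 1: 1 voxel, missed
        truth = np.zeros((2, 3, 3), dtype=np.uint8)
        truth[0] = 1
        truth[1, 0, 0] = 1
        pred = np.zeros_like(truth)
        pred[0] = 1
        slice_dices = [dice_2d(pred[z], truth[z]) for z in range(2)]
        # voxel-count oracle: 2*9/(9+10)
        assert dice_3d(pred, truth) == pytest.approx(18 / 19)
        assert dice_3d(pred, truth) > np.mean(slice_dices)

    def test_edge_failure_masked_by_volume_dice(self):
        # large central slices correct, small edge slices wrong: the
        # volumetric score hides what the slice-mean exposes
        truth = np.zeros((5, 8, 8), dtype=np.uint8)
        truth[0, 0, 0] = 1
        truth[1:4, 2:6, 2:6] = 1
        truth[4, 7, 7] = 1
        pred = truth.copy()
        pred[0] = 0
        pred[4] = 0
        slice_mean = np.mean([dice_2d(pred[z], truth[z]) for z in range(5)])
        assert dice_3d(pred, truth) > slice_mean


class TestSensitivitySpecificity:
    def test_perfect(self):
        m = mask_from_points([(1, 1), (2, 2)])
        assert sensitivity_slice(m, m) == 1.0
        assert specificity_slice(m, m) == 1.0

    def test_all_positive_prediction(self):
        truth = np.zeros((2, 2), dtype=np.uint8)
        truth[0] = 1
        pred = np.ones((2, 2), dtype=np.uint8)
        assert sensitivity_slice(pred, truth) == 1.0
        assert specificity_slice(pred, truth) == 0.0

    def test_hand_counts(self):
        # TP=3, FN=1, TN=10, FP=2 on a 4x4 slice
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[0, :4] = 1  # 4 positives
        pred = np.zeros((4, 4), dtype=np.uint8)
        pred[0, :3] = 1  # 3 TP, 1 FN
        pred[1, :2] = 1  # 2 FP
        assert sensitivity_slice(pred, truth) == pytest.approx(0.75)
        assert specificity_slice(pred, truth) == pytest.approx(10 / 12)

    def test_empty_truth_sensitivity_undefined(self):
        assert np.isnan(sensitivity_slice(np.zeros((2, 2)), np.zeros((2, 2))))


class TestHausdorff:
    def test_identical_zero(self):
        m = mask_from_points([(1, 2), (3, 4)])
        assert hausdorff_slice(m, m) == 0.0

    def test_three_four_five(self):
        assert hausdorff_slice(mask_from_points([(0, 0)]), mask_from_points([(3, 4)])) == pytest.approx(5.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = [tuple(p) for p in rng.integers(0, 10, size=(10, 2))]
            b = [tuple(p) for p in rng.integers(0, 10, size=(10, 2))]
            ma, mb = mask_from_points(a, (10, 10)), mask_from_points(b, (10, 10))
            pa = np.argwhere(ma)
            pb = np.argwhere(mb)
            # exhaustive all-pairs directed distances
            d_ab = max(min(np.hypot(*(p - q)) for q in pb) for p in pa)
            d_ba = max(min(np.hypot(*(q - p)) for p in pa) for q in pb)
            assert hausdorff_slice(ma, mb) == pytest.approx(max(d_ab, d_ba))

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(4)
        masks = [
            mask_from_points([tuple(p) for p in rng.integers(0, 8, size=(4, 2))])
            for _ in range(3)
        ]
        a, b, c = masks
        assert hausdorff_slice(a, b) == pytest.approx(hausdorff_slice(b, a))
        assert hausdorff_slice(a, c) <= hausdorff_slice(a, b) + hausdorff_slice(b, c) + 1e-9

    def test_empty_undefined(self):
        assert np.isnan(hausdorff_slice(np.zeros((3, 3)), mask_from_points([(1, 1)], (3, 3))))


class TestOffsetStratification:
    def make_table(self, dscs_by_offset, patient=0):
        rows = []
        for off, d in dscs_by_offset.items():
            rows.append(
                {
                    "patient": patient,
                    "z": off + 5,
                    "offset": off,
                    "dsc": d,
                    "sensitivity": d,
                    "specificity": 1.0,
                    "hausdorff_px": np.nan if d == 0 else 1.0,
                    "gtv_area_px": 10,
                    "in_gtv_span": True,
                }
            )
        return pd.DataFrame(rows)

    def test_flat_curve(self):
        t = self.make_table({-1: 0.7, 0: 0.7, 1: 0.7})
        curve = metrics_by_offset(t)
        assert np.allclose(curve["dsc"], 0.7)

    def test_exact_means(self):
        curve = metrics_by_offset(self.make_table({-1: 0.4, 0: 0.8, 1: 0.6})).set_index("offset")
        assert curve.loc[-1, "dsc"] == pytest.approx(0.4)
        assert curve.loc[0, "dsc"] == pytest.approx(0.8)
        assert curve.loc[1, "dsc"] == pytest.approx(0.6)

    def test_two_patient_average(self):
        t = [self.make_table({0: 0.8, 1: 0.6}, patient=0), self.make_table({0: 0.4, 1: 0.2}, patient=1)]
        curve = metrics_by_offset(t).set_index("offset")
        assert curve.loc[0, "dsc"] == pytest.approx(0.6)
        assert curve.loc[1, "dsc"] == pytest.approx(0.4)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            metrics_by_offset([])


class TestAreaAndDrift:
    def test_area_values(self):
        mask = np.zeros((3, 5, 5), dtype=np.uint8)
        mask[1] = 1  # full 5x5 square
        prof = area_profile(GtvMask(mask=mask, center_z=1)).set_index("offset")["area_px"]
        assert prof.loc[0] == 25
        assert prof.loc[-1] == 0 and prof.loc[1] == 0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            area_profile(GtvMask(mask=np.zeros((2, 2, 2), dtype=np.uint8), center_z=0))

    def test_static_mask_zero_drift(self):
        mask = np.zeros((4, 6, 6), dtype=np.uint8)
        mask[:, 2:4, 2:4] = 1
        assert centroid_drift_stats(mask) == (0.0, 0.0)

    def test_known_shift_recovered(self):
        mask = np.zeros((4, 8, 16), dtype=np.uint8)
        for z in range(4):
            mask[z, 2:4, 2 + 2 * z : 4 + 2 * z] = 1  # 2 px right per slice
        dy, dx = centroid_drift_stats(mask)
        assert (dy, dx) == (0.0, 2.0)

    def test_too_few_slices_errors(self):
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[0, 1, 1] = 1
        with pytest.raises(ValueError):
            centroid_drift_stats(mask)


class TestSliceMetricsTable:
    def test_table_contents(self):
        truth = np.zeros((4, 4, 4), dtype=np.uint8)
        truth[1, 1:3, 1:3] = 1
        truth[2, 1:3, 1:3] = 1
        pred = truth.copy()
        pred[2] = 0
        table = slice_metrics_table(pred, GtvMask(mask=truth, center_z=1), patient="p0")
        assert len(table) == 4
        row1 = table[table.z == 1].iloc[0]
        assert row1.dsc == 1.0 and row1.offset == 0
        row2 = table[table.z == 2].iloc[0]
        assert row2.dsc == 0.0 and row2.in_gtv_span
        assert not table[table.z == 0].iloc[0].in_gtv_span


class TestMetricProperties:
    """Hypothesis-driven invariants of the overlap metrics."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @given(arrays(np.uint8, (6, 6), elements=st.integers(0, 1)),
           arrays(np.uint8, (6, 6), elements=st.integers(0, 1)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dice_symmetric_bounded_and_reflexive(self, a, b):
        d = dice_2d(a, b)
        assert d == dice_2d(b, a)
        assert 0.0 <= d <= 1.0
        assert dice_2d(a, a) == 1.0

    @given(arrays(np.float32, (3, 4, 4), elements=st.floats(0, 1, width=32)),
           arrays(np.uint8, (3, 4, 4), elements=st.integers(0, 1)))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dice_loss_bounded(self, probs, truth):
        loss = float(dice_loss_2d(probs, truth.astype(np.float32)).data)
        assert -1e-6 <= loss <= 1.0 + 1e-6
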