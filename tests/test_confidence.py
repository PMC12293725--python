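"""Thresholds, confident assignment, confident joint, noise transition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pixelcl import (
    ConfidentJoint,
    LabelMask,
    ProbMap,
    ThresholdVector,
    UNASSIGNED,
    compute_confident_joint,
    compute_confident_joint_multi,
    compute_thresholds,
    confident_assignment,
    estimate_noise_transition,
)
from conftest import random_mask, random_probmap


class TestThresholds:
    def test_mean_of_self_probabilities(self, schema2):
        # three class-1 pixels with self-probs 0.8/0.9/1.0 -> t_1 = 0.9
        stack = np.array([[[0.2, 0.8], [0.1, 0.9]], [[0.0, 1.0], [1.0, 0.0]]])
        mask = LabelMask(np.array([[1, 1], [1, 0]]), schema2)
        t = compute_thresholds(ProbMap(stack, schema2), mask)
        assert t.values[1] == pytest.approx(0.9)
        assert t.values[0] == pytest.approx(1.0)  # single class-0 pixel at 1.0

    def test_pooling_weights_pixels_not_images(self, schema2):
        # map A: one class-1 pixel with p=0.6; map B: three with p=1.0
        # pooled mean = (0.6 + 3*1.0)/4 = 0.9, not (0.6 + 1.0)/2 = 0.8
        a = ProbMap(np.array([[[0.4, 0.6]]]), schema2)
        b = ProbMap(np.array([[[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]]), schema2)
        masks = [LabelMask(np.array([[1]]), schema2),
                 LabelMask(np.array([[1, 1, 1]]), schema2)]
        t = compute_thresholds([a, b], masks)
        assert t.values[1] == pytest.approx(0.9)

    def test_unlabeled_class_undefined(self, schema3):
        prob = ProbMap(np.full((2, 2, 3), 1 / 3), schema3)
        mask = LabelMask(np.zeros((2, 2), dtype=int), schema3)
        t = compute_thresholds(prob, mask)
        assert np.isnan(t.values[1]) and np.isnan(t.values[2])
        assert t.defined.tolist() == [True, False, False]

    def test_partition_invariance(self, schema3):
        # thresholds over one map equal thresholds pooled over its tiles
        rng = np.random.default_rng(11)
        prob = random_probmap(rng, (8, 8), schema3)
        mask = LabelMask(rng.integers(0, 3, size=(8, 8)), schema3)
        whole = compute_thresholds(prob, mask)
        tiles_p = [ProbMap(prob.stack[:4], schema3), ProbMap(prob.stack[4:], schema3)]
        tiles_m = [LabelMask(mask.grid[:4], schema3), LabelMask(mask.grid[4:], schema3)]
        tiled = compute_thresholds(tiles_p, tiles_m)
        np.testing.assert_allclose(whole.values, tiled.values, atol=1e-12)

    def test_shape_mismatch_rejected(self, schema2):
        prob = ProbMap(np.full((2, 2, 2), 0.5), schema2)
        mask = LabelMask(np.zeros((3, 3), dtype=int), schema2)
        with pytest.raises(ValueError):
            compute_thresholds(prob, mask)


class TestConfidentAssignment:
    def test_one_hot_assigned_to_its_class(self, schema3):
        t = ThresholdVector(np.array([0.9, 0.9, 0.9]), schema3)
        assert confident_assignment([0.0, 1.0, 0.0], t) == 1

    def test_both_eligible_max_wins(self, schema2):
        # eligible set {0, 1} by hand; argmax of (0.6, 0.4) -> class 0
        t = ThresholdVector(np.array([0.5, 0.3]), schema2)
        assert confident_assignment([0.6, 0.4], t) == 0

    def test_empty_eligible_set_unassigned(self, schema2):
        t = ThresholdVector(np.array([0.95, 0.95]), schema2)
        assert confident_assignment([0.5, 0.5], t) == UNASSIGNED

    def test_probability_equal_to_threshold_is_eligible(self, schema2):
        t = ThresholdVector(np.array([0.6, 0.9]), schema2)
        assert confident_assignment([0.6, 0.4], t) == 0

    def test_undefined_threshold_class_ineligible(self, schema2):
        t = ThresholdVector(np.array([np.nan, 0.5]), schema2)
        assert confident_assignment([0.9, 0.1], t) == UNASSIGNED

    def test_tie_broken_toward_lowest_id(self, schema2):
        t = ThresholdVector(np.array([0.3, 0.3]), schema2)
        assert confident_assignment([0.5, 0.5], t) == 0


class TestConfidentJoint:
    def test_agreeing_one_hot_gives_diagonal(self, schema2):
        grid = np.array([[0, 1], [1, 1]])
        prob = ProbMap(np.eye(2)[grid], schema2)
        t = ThresholdVector(np.array([0.5, 0.5]), schema2)
        joint, grid_out = compute_confident_joint(prob, LabelMask(grid, schema2), t)
        np.testing.assert_array_equal(joint.counts, [[1, 0], [0, 3]])
        assert joint.excluded == 0
        np.testing.assert_array_equal(grid_out.grid, grid)

    def test_four_pixel_hand_trace(self, toy4):
        probs, mask, thr = toy4
        t = ThresholdVector(thr, mask.schema)
        joint, grid = compute_confident_joint(probs, mask, t)
        np.testing.assert_array_equal(joint.counts, [[1, 0], [1, 1]])
        assert joint.excluded == 1
        assert grid.grid[0, 1] == UNASSIGNED

    def test_conservation_on_random_inputs(self, schema3):
        rng = np.random.default_rng(21)
        for _ in range(20):
            prob = random_probmap(rng, (9, 7), schema3)
            mask = LabelMask(rng.integers(0, 3, size=(9, 7)), schema3)
            t = ThresholdVector(rng.random(3), schema3)
            joint, _ = compute_confident_joint(prob, mask, t)
            assert joint.counts.sum() + joint.excluded == 63

    def test_multi_image_accumulation(self, schema2, toy4):
        probs, mask, thr = toy4
        t = ThresholdVector(thr, schema2)
        single, _ = compute_confident_joint(probs, mask, t)
        double, grids = compute_confident_joint_multi([probs, probs], [mask, mask], t)
        np.testing.assert_array_equal(double.counts, 2 * single.counts)
        assert double.excluded == 2 * single.excluded
        assert len(grids) == 2

    def test_zero_thresholds_match_bruteforce_confusion(self, schema3):
        # independent oracle: plain double-loop argmax confusion counter
        rng = np.random.default_rng(33)
        prob = random_probmap(rng, (16, 16), schema3)
        mask = LabelMask(rng.integers(0, 3, size=(16, 16)), schema3)
        t = ThresholdVector(np.zeros(3), schema3)
        joint, _ = compute_confident_joint(prob, mask, t)
        expected = np.zeros((3, 3), dtype=int)
        for r in range(16):
            for c in range(16):
                expected[mask.grid[r, c], int(np.argmax(prob.stack[r, c]))] += 1
        np.testing.assert_array_equal(joint.counts, expected)
        assert joint.excluded == 0

    def test_printed_orientation_round_trip(self):
        printed = np.array([[5, 1], [2, 7]])
        joint = ConfidentJoint.from_true_by_observed(printed, excluded=3)
        np.testing.assert_array_equal(joint.counts, printed.T)
        np.testing.assert_array_equal(joint.to_true_by_observed(), printed)
        assert joint.total_pixels == 18


class TestNoiseTransition:
    def test_identical_masks_give_identity(self, schema3):
        rng = np.random.default_rng(5)
        mask = LabelMask(rng.integers(0, 3, size=(20, 20)), schema3)
        T = estimate_noise_transition(mask, mask).matrix
        np.testing.assert_allclose(T, np.eye(3), atol=1e-12)

    def test_hand_counted_column(self, schema2):
        # 8 reference-background pixels, 2 observed as vessel -> column (0.75, 0.25)
        ref = LabelMask(np.zeros((2, 4), dtype=int), schema2)
        obs = LabelMask(np.array([[0, 0, 1, 0], [0, 1, 0, 0]]), schema2)
        T = estimate_noise_transition(obs, ref).matrix
        np.testing.assert_allclose(T[:, 0], [0.75, 0.25])
        assert np.isnan(T[:, 1]).all()  # no reference-vessel pixels

    def test_defined_columns_sum_to_one(self, schema3):
        rng = np.random.default_rng(6)
        obs = LabelMask(rng.integers(0, 3, size=(30, 30)), schema3)
        ref = LabelMask(rng.integers(0, 3, size=(30, 30)), schema3)
        T = estimate_noise_transition(obs, ref).matrix
        np.testing.assert_allclose(T.sum(axis=0), 1.0, atol=1e-9)

    def test_misaligned_pair_rejected(self, schema2):
        obs = LabelMask(np.zeros((2, 2), dtype=int), schema2)
        ref = LabelMask(np.zeros((3, 3), dtype=int), schema2)
        with pytest.raises(ValueError, match="misaligned"):
            estimate_noise_transition(obs, ref)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_property_conservation_any_seed(seed):
    """Joint counts plus excluded always equal the pixel count processed."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 6))
    shape = (int(rng.integers(1, 12)), int(rng.integers(1, 12)))
    mask = random_mask(rng, shape, m)
    prob = random_probmap(rng, shape, mask.schema)
    t = ThresholdVector(rng.random(m), mask.schema)
    joint, grid = compute_confident_joint(prob, mask, t)
    assert joint.counts.sum() + joint.excluded == shape[0] * shape[1]
    assert int(grid.unassigned.sum()) == joint.excluded
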