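import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lenseg.losses import (
    LossConfig,
    PredictionTarget,
    downsample_gt,
    iou_loss,
    literal_loss_floor,
    one_hot,
    pixel_ce,
    total_loss,
)


def brute_force_literal(p, q):
    """Independent per-pixel evaluation of the printed loss form."""
    k, h, w = p.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            sp = np.exp(p[:, i, j]) / np.exp(p[:, i, j]).sum()
            sq = np.exp(q[:, i, j]) / np.exp(q[:, i, j]).sum()
            total += -(sq * np.log(sp)).sum()
    return total / (h * w)


class TestPixelCE:
    @pytest.mark.parametrize("mode", ["literal_eq1", "hard_onehot"])
    def test_uniform_logits_give_ln_k(self, mode):
        p = np.zeros((3, 4, 4))
        q = one_hot(np.random.default_rng(0).integers(0, 3, (4, 4)), 3)
        loss = pixel_ce(PredictionTarget(p, q), mode).item()
        assert np.isclose(loss, np.log(3.0))

    def test_literal_single_pixel_worked_case(self):
        # q = p = (1, 0): loss is the entropy of softmax((1,0)) ~ 0.5822
        p = np.array([1.0, 0.0]).reshape(2, 1, 1)
        q = np.array([1.0, 0.0]).reshape(2, 1, 1)
        loss = pixel_ce(PredictionTarget(p, q), "literal_eq1").item()
        assert abs(loss - 0.5822) < 1e-3
        assert np.isclose(loss, brute_force_literal(p, q))

    def test_hard_onehot_closed_form(self):
        # -log softmax((2,0,0))[0] = ln(1 + 2 e^-2)
        p = np.array([2.0, 0.0, 0.0]).reshape(3, 1, 1)
        q = one_hot(np.zeros((1, 1), dtype=int), 3)
        loss = pixel_ce(PredictionTarget(p, q), "hard_onehot").item()
        assert np.isclose(loss, np.log(1 + 2 * np.exp(-2)))
        assert abs(loss - 0.2395) < 1e-3

    def test_literal_agrees_with_brute_force(self, rng):
        p = rng.normal(size=(3, 5, 6))
        q = one_hot(rng.integers(0, 3, (5, 6)), 3)
        ours = pixel_ce(PredictionTarget(p, q), "literal_eq1").item()
        assert np.isclose(ours, brute_force_literal(p, q))

    def test_literal_floor_for_onehot_targets(self):
        floor = literal_loss_floor(3)
        assert abs(floor - 0.9754) < 1e-3
        # equality at the floor: softmax(p) == softmax(q) when p == q
        q = one_hot(np.array([[0, 1], [2, 0]]), 3)
        at_floor = pixel_ce(PredictionTarget(q.copy(), q), "literal_eq1").item()
        assert np.isclose(at_floor, floor)
        # any perturbation increases the loss
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = q + rng.normal(0, 0.3, size=q.shape)
            assert pixel_ce(PredictionTarget(p, q), "literal_eq1").item() > floor

    def test_hard_loss_vanishes_with_confident_logits(self):
        q = one_hot(np.array([[1]]), 3)
        losses = [
            pixel_ce(PredictionTarget(q * scale, q), "hard_onehot").item()
            for scale in (5.0, 20.0, 50.0)
        ]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PredictionTarget(np.zeros((3, 2, 2)), np.zeros((3, 2, 3)))
        with pytest.raises(ValueError):
            PredictionTarget(np.zeros((3, 2, 2)), np.full((3, 2, 2), 2.0))


class TestDownsampleGT:
    def test_identity_at_same_size(self, rng):
        q = one_hot(rng.integers(0, 3, (6, 6)), 3)
        assert np.allclose(downsample_gt(q, 6, 6), q)

    def test_constant_field_any_size(self):
        q = np.zeros((3, 8, 8))
        q[1] = 1.0
        out = downsample_gt(q, 3, 5)
        assert out.shape == (3, 3, 5)
        assert np.allclose(out[1], 1.0) and np.allclose(out[0], 0.0)

    def test_checkerboard_to_single_pixel_averages(self):
        labels = np.array([[0, 1], [1, 0]])
        out = downsample_gt(one_hot(labels, 2), 1, 1)
        assert np.allclose(out[:, 0, 0], [0.5, 0.5])

    def test_hard_mode_returns_onehot(self, rng):
        q = one_hot(rng.integers(0, 3, (8, 8)), 3)
        out = downsample_gt(q, 4, 4, mode="hard_onehot")
        assert set(np.unique(out)) <= {0.0, 1.0}
        assert np.allclose(out.sum(axis=0), 1.0)

    def test_zero_target_dims_rejected(self):
        with pytest.raises(ValueError):
            downsample_gt(np.zeros((3, 4, 4)), 0, 2)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(2, 12), st.integers(2, 12), st.integers(1, 6), st.integers(1, 6))
    def test_partition_of_unity_preserved(self, h, w, th, tw):
        if th > h or tw > w:
            return
        rng = np.random.default_rng(h * 100 + w * 10 + th + tw)
        q = one_hot(rng.integers(0, 3, (h, w)), 3)
        out = downsample_gt(q, th, tw)
        assert np.all(out >= 0) and np.all(out <= 1)
        assert np.allclose(out.sum(axis=0), 1.0)


class TestTotalLoss:
    def test_paper_weights_arithmetic(self):
        cfg = LossConfig(aux_weights=(0.2, 0.3))
        assert np.isclose(total_loss(1.0, [1.0, 1.0], cfg), 1.5)

    def test_zero_aux_equals_main(self):
        cfg = LossConfig(aux_weights=(0.2, 0.3))
        assert total_loss(0.7, [0.0, 0.0], cfg) == 0.7

    def test_linearity(self, rng):
        cfg = LossConfig(aux_weights=(0.2, 0.3))
        m, a1, a2 = rng.uniform(0, 2, 3)
        assert np.isclose(
            total_loss(2 * m, [2 * a1, 2 * a2], cfg),
            2 * total_loss(m, [a1, a2], cfg),
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, [1.0], LossConfig(aux_weights=(0.2, 0.3)))

    def test_decreasing_weights_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(aux_weights=(0.5, 0.2))


class TestIoULoss:
    def test_perfect_prediction_zero_loss(self):
        q = one_hot(np.array([[0, 1], [1, 2]]), 3)
        p = np.where(q > 0, 80.0, -80.0)
        assert iou_loss(PredictionTarget(p, q)).item() < 1e-6

    def test_disjoint_prediction_near_one(self):
        labels = np.zeros((6, 6), dtype=int)
        q = one_hot(labels, 2)
        p = np.where(one_hot(1 - labels, 2) > 0, 80.0, -80.0)
        assert iou_loss(PredictionTarget(p, q)).item() > 0.999

    def test_uniform_prediction_hand_computed(self):
        # 1x2 image, q=[(1,0),(0,1)], uniform p: per-class soft IoU = 1/3
        q = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        p = np.zeros((2, 1, 2))
        assert np.isclose(iou_loss(PredictionTarget(p, q)).item(), 2.0 / 3.0, atol=1e-6)
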