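"""Loss algebra: closed forms, hand arithmetic, a plain-loop oracle and
the no-gradient-into-targets contract."""

import math

import numpy as np
import pytest

from mdcl import losses
from mdcl.autodiff import Tensor
from mdcl.losses import (
    LossReport,
    LossWeights,
    ce_loss,
    dice_loss,
    supervised_loss,
    total_loss,
    unsupervised_loss,
)

# ----------------------------------------------------------------------
# independent plain-loop reference implementations (scalar arithmetic)
# ----------------------------------------------------------------------


def ce_loop(pred, target, floor=1e-12):
    total, n = 0.0, 0
    for i in np.ndindex(target.shape):
        p = pred[(i[0], target[i]) + i[1:]]
        total += -math.log(max(p, floor))
        n += 1
    return total / n


def dice_loop(pred, target, smooth):
    vals = []
    for b in range(target.shape[0]):
        inter = psum = tsum = 0.0
        for i in np.ndindex(target.shape[1:]):
            p = pred[(b, 1) + i]
            t = 1.0 if target[(b,) + i] == 1 else 0.0
            inter += p * t
            psum += p
            tsum += t
        vals.append(1.0 - (2.0 * inter + smooth) / (psum + tsum + smooth))
    return sum(vals) / len(vals)


def random_instance(rng, shape=(4, 4, 2), batch=2):
    logits = rng.normal(size=(batch, 2) + shape)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    pred = e / e.sum(axis=1, keepdims=True)
    target = (rng.random((batch,) + shape) < 0.4).astype(np.int64)
    return pred, target


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        target = np.array([[0, 1], [1, 0]])
        pred = np.eye(2)[target].transpose(2, 0, 1)
        assert float(ce_loss(pred, target, batched=False)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_two_class_gives_log2(self):
        pred = np.full((2, 3, 3), 0.5)
        target = np.zeros((3, 3), dtype=int)
        assert float(ce_loss(pred, target, batched=False)) == pytest.approx(math.log(2), rel=1e-9)

    def test_hand_arithmetic_2x2(self):
        pred = np.array([[[0.9, 0.8], [0.6, 0.7]], [[0.1, 0.2], [0.4, 0.3]]])
        target = np.array([[0, 0], [1, 0]])
        expected = -np.mean(np.log([0.9, 0.8, 0.4, 0.7]))
        assert float(ce_loss(pred, target, batched=False)) == pytest.approx(expected, rel=1e-12)

    def test_zero_probability_floored_not_infinite(self):
        pred = np.stack([np.ones((2, 2)), np.zeros((2, 2))])
        target = np.ones((2, 2), dtype=int)  # target class has probability 0
        val = float(ce_loss(pred, target, batched=False))
        assert np.isfinite(val) and val == pytest.approx(-math.log(1e-12), rel=1e-6)

    def test_invalid_target_values_rejected(self):
        pred = np.full((2, 2, 2), 0.5)
        with pytest.raises(ValueError):
            ce_loss(pred, np.full((2, 2), 2), batched=False)


class TestDice:
    def test_perfect_overlap_is_smoothing_limited(self):
        target = np.array([[1, 0], [0, 1]])
        pred = np.stack([1.0 - target, target]).astype(float)
        assert float(dice_loss(pred, target, batched=False)) == pytest.approx(0.0, abs=1e-5)

    def test_empty_empty_convention_zero(self):
        pred = np.stack([np.ones((3, 3)), np.zeros((3, 3))])
        target = np.zeros((3, 3), dtype=int)
        assert float(dice_loss(pred, target, batched=False)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_half_overlap(self):
        fg = np.array([1.0, 1, 0, 0]).reshape(2, 2)
        pred = np.stack([1 - fg, fg])
        target = np.array([0, 1, 1, 0]).reshape(2, 2)
        val = float(dice_loss(pred, target, smooth=1e-12, batched=False))
        assert val == pytest.approx(0.5, abs=1e-9)

    def test_value_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pred, target = random_instance(rng)
            v = float(dice_loss(pred, target, batched=True))
            assert 0.0 <= v <= 1.0


class TestCompound:
    def test_weighted_sum_arithmetic(self):
        rep = LossReport(l_ce=1.0, l_dice=0.5, l_sup=0.3 * 1.0 + 0.7 * 0.5)
        assert rep.l_sup == pytest.approx(0.65)
        assert total_loss(rep, 0.2) == pytest.approx(0.85)

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 1.0])
    def test_alpha_boundaries_and_identity(self, alpha):
        rng = np.random.default_rng(1)
        pred, target = random_instance(rng)
        rep = supervised_loss(pred, target, LossWeights(alpha=alpha), batched=True)
        assert rep.l_sup == pytest.approx(alpha * rep.l_ce + (1 - alpha) * rep.l_dice, abs=1e-7)
        if alpha == 1.0:
            assert rep.l_sup == pytest.approx(rep.l_ce, abs=1e-12)
        if alpha == 0.0:
            assert rep.l_sup == pytest.approx(rep.l_dice, abs=1e-12)

    def test_unsupervised_equals_dice_bitwise(self):
        rng = np.random.default_rng(2)
        pred, target = random_instance(rng)
        assert float(unsupervised_loss(pred, target, batched=True)) == float(
            dice_loss(pred, target, batched=True)
        )

    def test_unsupervised_rejects_nonbinary_pseudo(self):
        pred = np.full((1, 2, 2, 2, 2), 0.5)
        with pytest.raises(ValueError):
            unsupervised_loss(pred, np.full((1, 2, 2, 2), 2), batched=True)

    def test_confident_wrong_prediction_near_one(self):
        target = np.zeros((1, 2, 2, 2), dtype=int)  # all background
        pred = np.zeros((1, 2, 2, 2, 2))
        pred[:, 1] = 0.999
        pred[:, 0] = 0.001
        assert float(unsupervised_loss(pred, target, batched=True)) > 0.99

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=1.5)
        with pytest.raises(ValueError):
            LossWeights(dice_smooth=0.0)


class TestOracleEquivalence:
    def test_vectorized_agrees_with_plain_loops(self):
        """50 random 4x4x2 instances: vectorized losses match the scalar
        loop reference to 1e-6 and the report identities hold to 1e-7."""
        rng = np.random.default_rng(42)
        w = LossWeights(alpha=0.3)
        for _ in range(50):
            pred, target = random_instance(rng)
            rep = supervised_loss(pred, target, w, batched=True)
            assert rep.l_ce == pytest.approx(ce_loop(pred, target), abs=1e-6)
            assert rep.l_dice == pytest.approx(
                dice_loop(pred, target, w.dice_smooth), abs=1e-6
            )
            pseudo = (rng.random(target.shape) < 0.5).astype(np.int64)
            l_un = float(unsupervised_loss(pred, pseudo, smooth=w.dice_smooth, batched=True))
            assert l_un == pytest.approx(dice_loop(pred, pseudo, w.dice_smooth), abs=1e-6)
            assert rep.l_sup == pytest.approx(0.3 * rep.l_ce + 0.7 * rep.l_dice, abs=1e-7)
            assert total_loss(rep, l_un) == pytest.approx(rep.l_sup + l_un, abs=1e-7)


class TestGradientFlow:
    def test_gradients_flow_to_pred_never_to_targets(self):
        rng = np.random.default_rng(3)
        pred_np, target = random_instance(rng)
        pred = Tensor(pred_np, requires_grad=True)
        t_const = Tensor(target.astype(float))  # even wrapped targets get no grad
        rep = supervised_loss(pred, target, batched=True)
        rep.tensors["l_sup"].backward()
        assert pred.grad is not None and np.abs(pred.grad).max() > 0
        assert t_const.grad is None

    def test_losses_nonnegative_and_finite(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pred, target = random_instance(rng)
            rep = supervised_loss(pred, target, batched=True)
            for v in (rep.l_ce, rep.l_dice, rep.l_sup, rep.l_total):
                assert np.isfinite(v) and v >= 0
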