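"""Loss functions against scalar-loop oracles and algebraic identities."""

import math

import numpy as np
import pytest

from conftest import gradcheck
from seu2net.losses import (
    LossWeights,
    bce_loss,
    cross_entropy,
    dice_loss,
    mixture_loss,
    supervised_loss,
)
from seu2net.metrics import ConfusionCounts, accumulate, dice_coeff
from seu2net.nn import Tensor, softmax
from seu2net.nn.tensor import tsum


def random_probmap(rng, n=1, c=2, h=4, w=4):
    logits = rng.normal(size=(n, c, h, w))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def ce_oracle(pred, target):
    """Per-pixel python-loop cross-entropy."""
    n, c, h, w = pred.shape
    total = 0.0
    for i in range(n):
        for y in range(h):
            for x in range(w):
                total += -math.log(max(pred[i, target[i, y, x], y, x], 1e-12))
    return total / (n * h * w)


def bce_oracle(p_fg, target):
    total = 0.0
    for p, t in zip(p_fg.ravel(), target.ravel()):
        total += -(t * math.log(max(p, 1e-12)) + (1 - t) * math.log(max(1 - p, 1e-12)))
    return total / p_fg.size


def dice_oracle(p_fg, target, eps=1e-6):
    inter = float((p_fg * target).sum())
    return 1.0 - (2.0 * inter + eps) / (float(p_fg.sum()) + float(target.sum()) + eps)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        target = np.array([[[0, 1], [1, 0]]])
        pred = np.zeros((1, 2, 2, 2))
        pred[0, 0][target[0] == 0] = 1.0
        pred[0, 1][target[0] == 1] = 1.0
        assert cross_entropy(pred, target).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_ln2(self):
        pred = np.full((1, 2, 1, 2), 0.5)
        target = np.array([[[0, 1]]])
        assert cross_entropy(pred, target).item() == pytest.approx(math.log(2), rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            pred = random_probmap(rng, n=2)
            target = rng.integers(0, 2, size=(2, 4, 4))
            assert cross_entropy(pred, target).item() == pytest.approx(
                ce_oracle(pred, target), rel=1e-10)

    def test_rejects_unnormalized_input(self, rng):
        bad = np.full((1, 2, 2, 2), 0.6)
        with pytest.raises(ValueError, match="sum to 1"):
            cross_entropy(bad, np.zeros((1, 2, 2), dtype=int))


class TestDiceLoss:
    def test_perfect_hard_prediction_is_zero(self):
        target = np.array([[[1, 0], [1, 1]]])
        pred = np.stack([1 - target, target], axis=1).astype(float)
        assert dice_loss(pred, target).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_hard_masks_score_one(self):
        target = np.array([[[1, 1], [0, 0]]])
        flipped = 1 - target
        pred = np.stack([1 - flipped, flipped], axis=1).astype(float)
        assert dice_loss(pred, target).item() == pytest.approx(1.0, abs=1e-6)

    def test_soft_toy_case_hand_computed(self):
        # 2x2: p_fg = [[0.8, 0.2], [0.6, 0.4]], target = [[1, 0], [1, 0]]
        p_fg = np.array([[0.8, 0.2], [0.6, 0.4]])
        pred = np.stack([1 - p_fg, p_fg])[None]
        target = np.array([[[1, 0], [1, 0]]])
        inter = 0.8 + 0.6
        expected = 1 - (2 * inter + 1e-6) / (2.0 + 2.0 + 1e-6)
        assert dice_loss(pred, target).item() == pytest.approx(expected, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            pred = random_probmap(rng)
            target = rng.integers(0, 2, size=(1, 4, 4))
            assert dice_loss(pred, target).item() == pytest.approx(
                dice_oracle(pred[:, 1], target), rel=1e-9)

    def test_consistency_with_dice_coefficient_metric(self, rng):
        """dice_loss on hard masks equals 1 - dice_coeff from counts."""
        for _ in range(10):
            pred_mask = rng.integers(0, 2, size=(1, 6, 6))
            target = rng.integers(0, 2, size=(1, 6, 6))
            pred = np.stack([1 - pred_mask, pred_mask], axis=1).astype(float)
            counts = accumulate(pred_mask[0], target[0], ConfusionCounts())
            assert dice_loss(pred, target).item() == pytest.approx(
                1.0 - dice_coeff(counts), abs=1e-5)


class TestBCE:
    def test_confident_prediction_and_coin_flip(self):
        target = np.array([[[1, 0]]])
        assert bce_loss(target.astype(float), target).item() == pytest.approx(0.0, abs=1e-9)
        assert bce_loss(np.full((1, 1, 2), 0.5), target).item() == pytest.approx(
            math.log(2), rel=1e-12)

    def test_matches_loop_oracle_and_rank4_input(self, rng):
        for _ in range(20):
            pred = random_probmap(rng)
            target = rng.integers(0, 2, size=(1, 4, 4))
            expected = bce_oracle(pred[:, 1], target)
            assert bce_loss(pred[:, 1], target).item() == pytest.approx(expected, rel=1e-10)
            assert bce_loss(pred, target).item() == pytest.approx(expected, rel=1e-10)


class TestMixture:
    def test_default_weights(self):
        w = LossWeights()
        assert (w.w_ce, w.w_dice) == (0.7, 0.3)

    def test_weighted_sum_of_components(self, rng):
        pred = random_probmap(rng)
        target = rng.integers(0, 2, size=(1, 4, 4))
        expected = (0.7 * cross_entropy(pred, target).item()
                    + 0.3 * dice_loss(pred, target).item())
        assert mixture_loss(pred, target).item() == pytest.approx(expected, rel=1e-12)

    def test_linearity_under_weight_scaling(self, rng):
        pred = random_probmap(rng)
        target = rng.integers(0, 2, size=(1, 4, 4))
        doubled = mixture_loss(pred, target, LossWeights(1.4, 0.6)).item()
        assert doubled == pytest.approx(2 * mixture_loss(pred, target).item(), rel=1e-9)

    def test_all_losses_nonnegative(self, rng):
        for _ in range(25):
            pred = random_probmap(rng)
            target = rng.integers(0, 2, size=(1, 4, 4))
            for fn in (cross_entropy, dice_loss, bce_loss, mixture_loss):
                assert fn(pred, target).item() >= -1e-9


class TestSupervised:
    def _outputs(self, rng, k=6):
        fused = random_probmap(rng)
        sides = [random_probmap(rng) for _ in range(k)]
        return fused, sides

    def test_fused_only_flag_reproduces_mixture(self, rng):
        outputs = self._outputs(rng)
        target = rng.integers(0, 2, size=(1, 4, 4))
        assert supervised_loss(outputs, target, fused_only=True).item() == pytest.approx(
            mixture_loss(outputs[0], target).item(), rel=1e-12)

    def test_identical_outputs_give_seven_fold_loss(self, rng):
        fused = random_probmap(rng)
        target = rng.integers(0, 2, size=(1, 4, 4))
        total = supervised_loss((fused, [fused] * 6), target).item()
        assert total == pytest.approx(7 * mixture_loss(fused, target).item(), rel=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        target = rng.integers(0, 2, size=(1, 3, 3))
        logits = rng.normal(size=(1, 2, 3, 3))
        side_logits = rng.normal(size=(1, 2, 3, 3))

        def fn(lf, ls):
            return supervised_loss(
                (softmax(lf, axis=1), [softmax(ls, axis=1)] * 2), target)

        gradcheck(fn, [logits, side_logits], atol=1e-4)

    def test_descent_on_one_parameter_toy_model(self, rng):
        """Gradient descent on a single logit shift decreases every loss."""
        target = rng.integers(0, 2, size=(1, 4, 4))
        base = rng.normal(size=(1, 2, 4, 4))
        for mode in ("mixture", "ce", "dice", "bce"):
            theta = Tensor(np.zeros(()), requires_grad=True)
            losses = []
            for _ in range(15):
                shift = Tensor(np.stack([-np.ones((4, 4)), np.ones((4, 4))])[None]) * theta
                probs = softmax(Tensor(base) + shift, axis=1)
                from seu2net.losses import _single_loss

                loss = _single_loss(mode, probs, target, LossWeights())
                theta.zero_grad()
                loss.backward()
                losses.append(loss.item())
                theta.data = theta.data - 0.5 * theta.grad
            # theta moves foreground logits toward the target balance
            assert losses[-1] < losses[0]
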