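"""Training losses: cross-entropy, soft Dice, BCE, and the 0.7/0.3 mixture.

All losses accept either plain ndarrays or autodiff tensors and return a
scalar :class:`~seu2net.nn.Tensor` (use ``.item()`` for the float).
Predictions are probability maps — rank-4 (N, C, H, W) arrays that sum
to one over the class axis — and targets are rank-3 (N, H, W) integer
class masks.  Class 1 is the lesion foreground of the binary task.

The Dice loss is the standard Sorensen-Dice complement
``1 - (2 |A.B| + eps) / (|A| + |B| + eps)`` computed on soft foreground
probabilities with a small smoothing term guarding empty masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor
from .nn.tensor import log_clamped, mul, onehot_gather, tmean, tsum

__all__ = [
    "LossWeights",
    "cross_entropy",
    "dice_loss",
    "bce_loss",
    "mixture_loss",
    "supervised_loss",
    "LOSS_MODES",
]

LOG_EPS = 1e-12
DICE_EPS = 1e-6
PROB_TOL = 1e-4


@dataclass(frozen=True)
class LossWeights:
    """Mixture weights: 0.7 on cross-entropy, 0.3 on Dice."""

    w_ce: float = 0.7
    w_dice: float = 0.3

    def __post_init__(self):
        if self.w_ce < 0 or self.w_dice < 0:
            raise ValueError("loss weights must be non-negative")


def _check_probmap(pred: Tensor, target: np.ndarray | None = None) -> None:
    if pred.ndim != 4:
        raise ValueError(f"probability map must be rank-4 (N,C,H,W), got rank {pred.ndim}")
    sums = pred.data.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=PROB_TOL):
        raise ValueError("probability map does not sum to 1 over classes")
    if target is not None:
        if target.shape != (pred.shape[0],) + pred.shape[2:]:
            raise ValueError(f"target shape {target.shape} does not match prediction {pred.shape}")
        if target.max(initial=0) >= pred.shape[1]:
            raise ValueError("target contains a label >= num_classes")


def cross_entropy(pred, target: np.ndarray) -> Tensor:
    """Mean over pixels of the negative log probability of the true class."""
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.int64)
    _check_probmap(pred, target)
    p_true = onehot_gather(pred, target)
    return -tmean(log_clamped(p_true, LOG_EPS))


def dice_loss(pred, target: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice complement on the foreground (class 1) probabilities."""
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.int64)
    _check_probmap(pred, target)
    p_fg = onehot_gather(pred, np.ones_like(target))   # class-1 probability map
    t = (target == 1).astype(pred.dtype.type)
    inter = tsum(mul(p_fg, Tensor(t)))
    denom = tsum(p_fg) + float(t.sum())
    # 1 - (2*inter + eps)/(denom + eps), kept differentiable via 1/denom data
    two_inter = 2.0 * inter + eps
    return 1.0 - _ratio(two_inter, denom + eps)


def _ratio(num: Tensor, den: Tensor) -> Tensor:
    """num/den for scalar tensors with the quotient-rule gradient."""
    num, den = as_tensor(num), as_tensor(den)
    d = float(den.data)
    out = Tensor(num.data / d)
    if num.requires_grad or den.requires_grad or num._parents or den._parents:
        out.requires_grad = num.requires_grad or den.requires_grad

        def backward(g):
            num._accumulate(g / d)
            den._accumulate(-g * num.data / (d * d))

        out._parents = (num, den)
        out._backward = backward
    return out


def bce_loss(pred, target: np.ndarray) -> Tensor:
    """Per-pixel binary cross-entropy on the foreground probability.

    ``pred`` may be a rank-3 (N, H, W) foreground probability map or a
    rank-4 two-class probability map (channel 1 is used).
    """
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.int64)
    if pred.ndim == 4:
        _check_probmap(pred, target)
        pred = onehot_gather(pred, np.ones_like(target))
    elif pred.shape != target.shape:
        raise ValueError("foreground probability map must match target shape")
    t = (target == 1).astype(pred.dtype.type)
    loss = mul(Tensor(t), log_clamped(pred, LOG_EPS)) + mul(Tensor(1.0 - t), log_clamped(1.0 - pred, LOG_EPS))
    return -tmean(loss)


def mixture_loss(pred, target: np.ndarray, w: LossWeights | None = None) -> Tensor:
    """The weighted mixture 0.7 * cross-entropy + 0.3 * Dice."""
    w = w or LossWeights()
    return w.w_ce * cross_entropy(pred, target) + w.w_dice * dice_loss(pred, target)


def _single_loss(mode: str, pred, target, w: LossWeights) -> Tensor:
    if mode == "mixture":
        return mixture_loss(pred, target, w)
    if mode == "ce":
        return cross_entropy(pred, target)
    if mode == "dice":
        return dice_loss(pred, target)
    if mode == "bce":
        return bce_loss(pred, target)
    raise ValueError(f"unknown loss mode {mode!r}; choose from {sorted(LOSS_MODES)}")


LOSS_MODES = {"mixture", "ce", "dice", "bce"}


def supervised_loss(outputs, target: np.ndarray, w: LossWeights | None = None,
                    mode: str = "mixture", fused_only: bool = False) -> Tensor:
    """Deep-supervision objective: the selected loss summed over the
    fused map and all six side outputs (equally weighted), or over the
    fused map alone when ``fused_only`` is set.

    ``outputs`` is ``(fused, sides)`` as returned by the network forward
    pass, already converted to probability maps.
    """
    w = w or LossWeights()
    fused, sides = outputs
    total = _single_loss(mode, fused, target, w)
    if not fused_only:
        for s in sides:
            total = total + _single_loss(mode, s, target, w)
    return total
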