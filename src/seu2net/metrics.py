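"""Segmentation metrics from globally accumulated confusion counts.

Counts are accumulated per class over the whole evaluation split
(intersection, prediction and label pixel areas), and the four metrics
derive from them:

* IoU   = TP / (TP + FP + FN)                    (foreground class)
* Acc   = sum_c intersect_c / total pixels       (overall pixel accuracy)
* Kappa = (Acc - Pe) / (1 - Pe),  Pe = sum_c pred_c * label_c / total^2
* Dice  = 2 TP / (pred_fg + label_fg)            (foreground class)

Edge case: when neither prediction nor truth contains any foreground
over the accumulation, IoU and Dice are defined as 1 (perfect agreement
on absence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "accumulate",
    "iou",
    "accuracy",
    "kappa",
    "dice_coeff",
    "compute_report",
]

FOREGROUND = 1


@dataclass
class ConfusionCounts:
    """Per-class pixel tallies for a binary (background/lesion) task."""

    num_classes: int = 2
    intersect_area: np.ndarray = field(default=None)
    pred_area: np.ndarray = field(default=None)
    label_area: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.intersect_area is None:
            self.intersect_area = np.zeros(self.num_classes, dtype=np.int64)
            self.pred_area = np.zeros(self.num_classes, dtype=np.int64)
            self.label_area = np.zeros(self.num_classes, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.pred_area.sum())

    # foreground-class confusion cells
    @property
    def tp(self) -> int:
        return int(self.intersect_area[FOREGROUND])

    @property
    def fp(self) -> int:
        return int(self.pred_area[FOREGROUND] - self.intersect_area[FOREGROUND])

    @property
    def fn(self) -> int:
        return int(self.label_area[FOREGROUND] - self.intersect_area[FOREGROUND])

    @property
    def tn(self) -> int:
        return self.total - self.tp - self.fp - self.fn


@dataclass
class MetricReport:
    """The four evaluation metrics as fractions (see module docstring)."""

    iou: float
    acc: float
    kappa: float
    dice: float

    def in_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.__dict__.items()}


def accumulate(pred: np.ndarray, truth: np.ndarray,
               counts: ConfusionCounts | None = None) -> ConfusionCounts:
    """Add one prediction/truth pair (integer class masks, same shape)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}")
    counts = counts or ConfusionCounts()
    c = counts.num_classes
    if pred.max(initial=0) >= c or truth.max(initial=0) >= c:
        raise ValueError(f"mask contains a label >= num_classes ({c})")
    for k in range(c):
        pk = pred == k
        tk = truth == k
        counts.pred_area[k] += int(pk.sum())
        counts.label_area[k] += int(tk.sum())
        counts.intersect_area[k] += int((pk & tk).sum())
    return counts


def iou(counts: ConfusionCounts) -> float:
    union = counts.tp + counts.fp + counts.fn
    if union == 0:
        return 1.0  # no foreground anywhere: agreement on absence
    return counts.tp / union


def accuracy(counts: ConfusionCounts) -> float:
    total = counts.total
    if total == 0:
        raise ValueError("no pixels accumulated")
    return float(counts.intersect_area.sum()) / total


def kappa(counts: ConfusionCounts) -> float:
    total = counts.total
    if total == 0:
        raise ValueError("no pixels accumulated")
    acc = accuracy(counts)
    pe = float((counts.pred_area.astype(np.float64) * counts.label_area).sum()) / (total ** 2)
    if pe >= 1.0:
        return 0.0  # both marginals degenerate: no agreement beyond chance
    return (acc - pe) / (1.0 - pe)


def dice_coeff(counts: ConfusionCounts) -> float:
    denom = counts.pred_area[FOREGROUND] + counts.label_area[FOREGROUND]
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / float(denom)


def compute_report(counts: ConfusionCounts) -> MetricReport:
    return MetricReport(iou=iou(counts), acc=accuracy(counts),
                        kappa=kappa(counts), dice=dice_coeff(counts))
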