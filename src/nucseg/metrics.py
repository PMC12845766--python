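"""Pixelwise segmentation metrics.

All scores derive from the four confusion counts over pixels, with the
nucleus as the positive class:

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F1        = 2 * precision * recall / (precision + recall)
    IoU       = tp / (tp + fp + fn)

MeanIoU averages the foreground IoU with the background IoU
(tn / (tn + fp + fn)) — the two-class mean, computed by default from
confusion counts summed over the whole evaluation set (micro-average).
Degenerate 0/0 ratios are defined as 1.0: an image with no nuclei that
is predicted all-background is a perfect, if vacuous, segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    iou_foreground: float
    iou_background: float
    mean_iou: float
    accuracy: float

    def to_dict(self) -> dict[str, float]:
        """Keys named as in the standard benchmark-table layout."""
        return {
            "MIoU": self.mean_iou,
            "Precision": self.precision,
            "Recall": self.recall,
            "F-1 Score": self.f1,
            "IoU (foreground)": self.iou_foreground,
            "IoU (background)": self.iou_background,
            "Accuracy": self.accuracy,
        }


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts; 1 = nucleus, 0 = background."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != ground truth {gt.shape}")
    for name, arr in (("pred", pred), ("gt", gt)):
        if not np.isin(arr, [0, 1]).all():
            raise ValidationError(f"{name} must be binary 0/1")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    return ConfusionCounts(
        tp=int((pred & gt).sum()),
        tn=int((~pred & ~gt).sum()),
        fp=int((pred & ~gt).sum()),
        fn=int((~pred & gt).sum()),
    )


def _ratio(num: int, den: int) -> float:
    # 0/0 -> 1.0 by convention (vacuously perfect); den==0 implies num==0
    return num / den if den > 0 else 1.0


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive all scores from one set of confusion counts."""
    if c.total == 0:
        raise ValidationError("no pixels to evaluate")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    iou_fg = _ratio(c.tp, c.tp + c.fp + c.fn)
    iou_bg = _ratio(c.tn, c.tn + c.fp + c.fn)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        iou_foreground=iou_fg,
        iou_background=iou_bg,
        mean_iou=(iou_fg + iou_bg) / 2.0,
        accuracy=(c.tp + c.tn) / c.total,
    )


def threshold_prediction(prob_map: np.ndarray) -> np.ndarray:
    """Argmax over the channel axis; exact ties go to foreground.

    ``prob_map`` is (..., 2) with channel 1 = nucleus probability.
    """
    prob_map = np.asarray(prob_map)
    if prob_map.shape[-1] != 2:
        raise ValidationError(f"expected 2 channels, got {prob_map.shape[-1]}")
    return (prob_map[..., 1] >= prob_map[..., 0]).astype(np.uint8)


def aggregate(counts: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Micro-aggregation: sum counts before computing metrics."""
    total = ConfusionCounts(0, 0, 0, 0)
    for c in counts:
        total = total + c
    return total


def evaluate_batch(
    pred_masks: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    macro: bool = False,
) -> MetricsReport:
    """Score a set of predictions.

    Micro (default): sum confusion counts over all masks, then derive
    metrics. Macro: compute per-mask metrics and average them.
    """
    counts = [confusion(p, g) for p, g in zip(pred_masks, gt_masks)]
    if not macro:
        return compute_metrics(aggregate(counts))
    reports = [compute_metrics(c) for c in counts]
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    return MetricsReport(*(mean(f) for f in (
        "precision", "recall", "f1", "iou_foreground", "iou_background",
        "mean_iou", "accuracy")))
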