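"""Evaluation metrics: MAPE, RMSE, MAE, R², accuracies, and mAP@0.5.

Regression-style agreement between predicted and true trait values is
summarized by MAPE / RMSE / MAE / R²; categorical predictions (density
class, maturity stage) by accuracy and a confusion matrix; detector
quality by average precision at IoU 0.5 with all-point interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import DetectionSet
from .errors import DomainError, InputFormatError

__all__ = [
    "PairedSeries",
    "mape",
    "rmse",
    "mae",
    "r_squared",
    "class_accuracy",
    "ConfusionMatrix",
    "confusion_from_labels",
    "box_iou",
    "average_precision_50",
    "map50",
]


@dataclass(frozen=True)
class PairedSeries:
    """Equal-length actual/predicted value pairs."""

    actual: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.actual, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if a.shape != p.shape or a.ndim != 1 or a.size < 1:
            raise DomainError("actual/predicted must be equal-length 1-D, n >= 1")
        if not (np.isfinite(a).all() and np.isfinite(p).all()):
            raise DomainError("series contain non-finite values")
        object.__setattr__(self, "actual", a)
        object.__setattr__(self, "predicted", p)

    @property
    def n(self) -> int:
        return self.actual.size


def mape(s: PairedSeries) -> float:
    """Mean absolute percentage error, in percent. Zero actuals error out."""
    if np.any(s.actual == 0):
        raise DomainError("MAPE undefined: actual series contains 0")
    return float(np.mean(np.abs((s.actual - s.predicted) / s.actual)) * 100.0)


def rmse(s: PairedSeries) -> float:
    return float(np.sqrt(np.mean((s.actual - s.predicted) ** 2)))


def mae(s: PairedSeries) -> float:
    return float(np.mean(np.abs(s.actual - s.predicted)))


def r_squared(s: PairedSeries) -> float:
    """1 - SSE/SST; may be negative, never clipped."""
    sst = float(np.sum((s.actual - s.actual.mean()) ** 2))
    if sst == 0:
        raise DomainError("R² undefined: actual series is constant")
    sse = float(np.sum((s.actual - s.predicted) ** 2))
    return 1.0 - sse / sst


def class_accuracy(correct: int, total: int, decimals: int = 2) -> float:
    """Percentage accuracy rounded to ``decimals`` places."""
    if total <= 0:
        raise DomainError("total must be > 0")
    if not 0 <= correct <= total:
        raise DomainError(f"need 0 <= correct <= total, got {correct}/{total}")
    return round(100.0 * correct / total, decimals)


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: pd.DataFrame  # rows = true class, cols = predicted class

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts.values), index=self.counts.index, dtype=float)
        row_sums = self.counts.sum(axis=1)
        return 100.0 * diag / row_sums.replace(0, np.nan)

    @property
    def overall_accuracy(self) -> float:
        total = int(self.counts.values.sum())
        return 100.0 * float(np.trace(self.counts.values)) / total if total else float("nan")


def confusion_from_labels(
    true_labels, predicted_labels, classes: list | None = None
) -> ConfusionMatrix:
    """K×K confusion counts from parallel label lists."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise DomainError("label lists must have equal length")
    if classes is None:
        classes = sorted(set(true_labels) | set(predicted_labels))
    idx = {c: i for i, c in enumerate(classes)}
    bad = [l for l in true_labels + predicted_labels if l not in idx]
    if bad:
        raise InputFormatError(f"labels outside declared class set: {sorted(set(bad))}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(pd.DataFrame(counts, index=classes, columns=classes))


def box_iou(a: tuple, b: tuple) -> float:
    """IoU of two half-open (r0, c0, r1, c1) boxes."""
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def average_precision_50(
    dets: DetectionSet, gt_boxes: list[tuple], iou_threshold: float = 0.5, mode: str = "all_point"
) -> float:
    """Average precision at an IoU threshold (default 0.5).

    Detections are matched greedily in descending-confidence order, each
    ground-truth box consumed at most once. The precision-recall curve is
    integrated with all-point interpolation (area under the monotone
    envelope); ``mode="11_point"`` averages the interpolated precision at
    recalls 0, 0.1, ..., 1.
    """
    if not gt_boxes:
        raise DomainError("AP undefined: no ground-truth boxes")
    order = sorted(dets.detections, key=lambda d: -d.confidence)
    matched = [False] * len(gt_boxes)
    tp = np.zeros(len(order))
    for i, det in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gt_boxes):
            if matched[j]:
                continue
            iou = box_iou(det.box, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_iou >= iou_threshold:
            matched[best_j] = True
            tp[i] = 1.0
    if len(order) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / len(gt_boxes)
    precision = cum_tp / np.arange(1, len(order) + 1)
    # monotone precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if mode == "11_point":
        pts = []
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            pts.append(float(env[mask].max()) if mask.any() else 0.0)
        return float(np.mean(pts))
    # all-point: sum precision at each recall increment
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def map50(per_class_aps: list[float]) -> float:
    """Mean AP over classes."""
    if not per_class_aps:
        raise DomainError("mAP undefined: no classes")
    return float(np.mean(per_class_aps))
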