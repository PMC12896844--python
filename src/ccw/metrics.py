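"""Confusion-count segmentation metrics and min-max normalization.

All metrics are computed from per-class one-vs-rest pixel confusion counts
(TP, FP, FN, TN):

* ``IoU  = TP / (TP + FP + FN)``
* ``Dice = 2 TP / (2 TP + FP + FN)``  (equals F1 on binary masks)
* ``Precision = TP / (TP + FP)``, ``Recall = TP / (TP + FN)``,
  ``F1 = 2 P R / (P + R)``
* ``mIoU`` = mean IoU over a configurable category set (foreground classes
  by default; the background class can optionally be included).

Degenerate cases: a class absent from both prediction and ground truth is
excluded from means (and its per-class scores are reported as 1.0); when a
denominator vanishes but error mass exists, the score is 0.0.

Counts can be accumulated across images before the ratios are taken
(micro-averaging), which is how the evaluation loop aggregates a test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel counts; arrays of length K."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion(pred: np.ndarray, gt: np.ndarray, n_classes: int) -> ConfusionCounts:
    """Exact per-class pixel confusion counts for two label masks."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if pred.max(initial=0) >= n_classes or gt.max(initial=0) >= n_classes:
        raise ValueError(f"labels must be < n_classes = {n_classes}")
    cm = np.bincount(
        gt.ravel().astype(np.int64) * n_classes + pred.ravel().astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num: np.ndarray, den: np.ndarray, absent: np.ndarray) -> np.ndarray:
    """num/den with 0/0 -> 0, except classes absent from both sides -> 1."""
    out = np.zeros(len(num), dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[absent] = 1.0
    return out


def iou_dice(counts: ConfusionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-class IoU and Dice."""
    absent = (counts.tp + counts.fp + counts.fn) == 0
    iou = _safe_ratio(counts.tp, counts.tp + counts.fp + counts.fn, absent)
    dice = _safe_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, absent)
    return iou, dice


def miou(counts: ConfusionCounts, include_background: bool = False,
         background_class: int = 0) -> float:
    """Mean IoU over the category set (foreground-only by default).

    Classes absent from both prediction and ground truth are excluded from
    the mean.
    """
    iou, _ = iou_dice(counts)
    absent = (counts.tp + counts.fp + counts.fn) == 0
    keep = ~absent
    if not include_background:
        keep = keep.copy()
        keep[background_class] = False
    if not keep.any():
        return 1.0
    return float(iou[keep].mean())


def precision_recall_f1(
    counts: ConfusionCounts,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class precision, recall and their harmonic mean."""
    absent = (counts.tp + counts.fp + counts.fn) == 0
    p = _safe_ratio(counts.tp, counts.tp + counts.fp, absent)
    r = _safe_ratio(counts.tp, counts.tp + counts.fn, absent)
    f1 = np.zeros_like(p)
    nz = (p + r) > 0
    f1[nz] = 2 * p[nz] * r[nz] / (p[nz] + r[nz])
    f1[absent] = 1.0
    return p, r, f1


def minmax_normalize(x) -> np.ndarray:
    """Scale a vector to [0, 1]: x' = (x - min) / (max - min)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 1:
        raise ValueError("minmax_normalize requires at least one value")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("minmax_normalize undefined for a constant vector")
    return (x - lo) / (hi - lo)


def evaluate_masks(pairs, n_classes: int,
                   include_background: bool = False) -> dict:
    """Micro-aggregate metrics over an iterable of (pred, gt) mask pairs."""
    total = None
    for pred, gt in pairs:
        c = confusion(pred, gt, n_classes)
        total = c if total is None else total + c
    if total is None:
        raise ValueError("no mask pairs to evaluate")
    iou, dice = iou_dice(total)
    p, r, f1 = precision_recall_f1(total)
    return {
        "iou": iou, "dice": dice, "precision": p, "recall": r, "f1": f1,
        "miou": miou(total, include_background=include_background),
        "counts": total,
    }
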