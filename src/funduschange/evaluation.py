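"""Pixel-wise evaluation of change maps and masks against ground truth.

Confusion counts and the four standard rates::

    TPR = TP / (TP + FN)        FPR = FP / (TN + FP)
    Precision = TP / (TP + FP)  Recall = TP / (TP + FN)

(0/0 resolves to 0 by convention), threshold-sweep ROC and precision-recall
curves with AUC (trapezoidal over FPR-TPR) and mAP, and intersection-over-
union of binary masks.  An optional field-of-view mask restricts all counts
to the retina (fundus photographs have a black surround that would otherwise
inflate the true-negative count); without one, every pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .change_map import ChangeMap
from .image_io import DimensionError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_bool(arr, name) -> np.ndarray:
    return np.asarray(arr, dtype=bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")


def confusion(pred, truth, fov=None) -> ConfusionCounts:
    """Per-pixel confusion counts of a predicted mask against ground truth."""
    pred = _as_bool(pred, "pred")
    truth = _as_bool(truth, "truth")
    _check_shapes(pred, truth)
    if fov is not None:
        fov = _as_bool(fov, "fov")
        _check_shapes(pred, fov)
        pred, truth = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def rates(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(TPR, FPR, precision, recall); degenerate 0/0 denominators give 0."""
    tpr = _safe_div(c.tp, c.tp + c.fn)
    fpr = _safe_div(c.fp, c.tn + c.fp)
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = tpr
    return tpr, fpr, precision, recall


@dataclass(frozen=True)
class EvalCurves:
    """Threshold-sweep ROC / PR curves and their areas."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    map: float


def average_precision(precision: np.ndarray, recall: np.ndarray,
                      interpolated: bool = True) -> float:
    """Area under the PR curve.

    ``interpolated=True`` (default) integrates the precision envelope — for
    each recall level, the maximum precision at any recall >= it — which is
    the standard AP definition. ``interpolated=False`` integrates the raw
    step curve.
    """
    order = np.argsort(recall)
    r = np.concatenate(([0.0], np.asarray(recall)[order]))
    p = np.concatenate(([1.0], np.asarray(precision)[order]))
    if interpolated:
        p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * p[1:]))


def roc_pr_curves(score_map: ChangeMap | np.ndarray, truth,
                  fov=None, interpolated_map: bool = True) -> EvalCurves:
    """Sweep all distinct score values as thresholds; compute ROC and PR.

    ``score_map`` may be a ChangeMap (its rescaled absolute map is used) or
    a plain score array.  ``truth`` must contain at least one positive and
    one negative pixel inside the field of view.
    """
    scores = (score_map.absolute if isinstance(score_map, ChangeMap)
              else np.asarray(score_map, dtype=np.float64))
    truth = _as_bool(truth, "truth")
    _check_shapes(scores, truth)
    if fov is not None:
        fov = _as_bool(fov, "fov")
        _check_shapes(scores, fov)
        scores, truth = scores[fov], truth[fov]
    scores = scores.ravel()
    y = truth.ravel().astype(int)
    if y.min() == y.max():
        raise ValueError(
            "ground truth must contain both positive and negative pixels"
        )
    fpr, tpr, roc_thr = _skm.roc_curve(y, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    precision, recall, _ = _skm.precision_recall_curve(y, scores)
    ap = average_precision(precision, recall, interpolated=interpolated_map)
    return EvalCurves(thresholds=roc_thr, tpr=tpr, fpr=fpr,
                      precision=precision, recall=recall, auc=auc, map=ap)


def iou(pred, truth, fov=None) -> float:
    """Intersection over union of two masks; both empty gives 1.0."""
    pred = _as_bool(pred, "pred")
    truth = _as_bool(truth, "truth")
    _check_shapes(pred, truth)
    if fov is not None:
        fov = _as_bool(fov, "fov")
        _check_shapes(pred, fov)
        pred, truth = pred[fov], truth[fov]
    union = np.sum(pred | truth)
    if union == 0:
        return 1.0
    return float(np.sum(pred & truth) / union)


def evaluate_masks(pred, truth, score_map=None, fov=None) -> dict:
    """JSON-ready evaluation report for a predicted mask (and optional map)."""
    c = confusion(pred, truth, fov=fov)
    tpr, fpr, precision, recall = rates(c)
    report = {
        "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
        "tpr": tpr, "fpr": fpr, "precision": precision, "recall": recall,
        "iou": iou(pred, truth, fov=fov),
    }
    if score_map is not None:
        curves = roc_pr_curves(score_map, truth, fov=fov)
        report["auc"] = curves.auc
        report["map"] = curves.map
    return report
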