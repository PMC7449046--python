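"""Segmentation accuracy assessment: PA, IoU, per-class accuracy, ROC-AUC.

All pixel metrics derive from the 3x3 confusion matrix whose entry
``counts[i, j]`` is the number of pixels of true class *i* predicted as
class *j*:

* pixel accuracy      PA   = trace / total
* per-class accuracy  A_i  = p_ii / sum_j p_ij          (recall of class i)
* intersection/union  IoU_i = p_ii / (sum_j p_ij + sum_j p_ji - p_ii)
* mIoU               = mean of IoU_i over classes present in truth or
                       prediction (classes absent from both are excluded)

ROC analysis is one-vs-rest over pooled pixels, scoring each class by its
predicted probability; AUC uses trapezoidal integration, equivalent to the
Mann-Whitney statistic with the midpoint tie convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

N_CLASSES = 3


class EmptyMatrixError(ZeroDivisionError):
    """Metric requested on a confusion matrix with no pixels."""


def _labels_of(mask) -> np.ndarray:
    arr = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
    return np.asarray(arr)


def confusion(pred, truth) -> np.ndarray:
    """3x3 pixel-count matrix; rows are truth, columns prediction."""
    p = _labels_of(pred)
    t = _labels_of(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    for arr, name in ((p, "pred"), (t, "truth")):
        if arr.size and not np.isin(arr, (0, 1, 2)).all():
            raise ValueError(f"{name} labels must be in {{0, 1, 2}}")
    return np.bincount(
        (t.ravel() * N_CLASSES + p.ravel()).astype(np.int64),
        minlength=N_CLASSES * N_CLASSES,
    ).reshape(N_CLASSES, N_CLASSES)


def _check_nonempty(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise EmptyMatrixError("confusion matrix contains no pixels")
    return cm


def pixel_accuracy(cm: np.ndarray) -> float:
    """Proportion of correctly classified pixels."""
    cm = _check_nonempty(cm)
    return float(np.trace(cm) / cm.sum())


def iou_per_class(cm: np.ndarray) -> np.ndarray:
    """IoU per class; NaN for classes absent from both truth and prediction."""
    cm = _check_nonempty(cm)
    tp = np.diag(cm).astype(np.float64)
    union = cm.sum(axis=1) + cm.sum(axis=0) - tp
    with np.errstate(invalid="ignore"):
        return np.where(union > 0, tp / union, np.nan)


def mean_iou(cm: np.ndarray) -> float:
    """Class-mean IoU over the classes present in truth or prediction."""
    ious = iou_per_class(cm)
    return float(np.nanmean(ious))


def per_class_accuracy(cm: np.ndarray) -> np.ndarray:
    """Recall per true class; NaN where the class is absent from truth."""
    cm = _check_nonempty(cm)
    tp = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(support > 0, tp / support, np.nan)


def roc_auc(probmaps, truths):
    """One-vs-rest ROC over pooled pixels.

    ``probmaps``: list of (H, W, 3) probability maps (or one array);
    ``truths``: matching list of masks.  Returns ``(curves, auc_per_class,
    auc_macro)`` where curves[c] = (fpr, tpr).  A class absent from the
    pooled truth gets NaN AUC and is excluded from the macro mean.
    """
    if not isinstance(probmaps, (list, tuple)):
        probmaps = [probmaps]
    if not isinstance(truths, (list, tuple)):
        truths = [truths]
    if len(probmaps) != len(truths):
        raise ValueError("probmaps and truths must align")
    scores, labels = [], []
    for pm, tm in zip(probmaps, truths):
        pm = np.asarray(pm, dtype=np.float64)
        t = _labels_of(tm)
        if pm.shape[:-1] != t.shape or pm.shape[-1] != N_CLASSES:
            raise ValueError("probability map and mask shapes disagree")
        scores.append(pm.reshape(-1, N_CLASSES))
        labels.append(t.ravel())
    scores = np.concatenate(scores)
    labels = np.concatenate(labels)
    curves, aucs = [], np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        positive = labels == c
        if positive.all() or not positive.any():
            curves.append((np.array([0.0, 1.0]), np.array([0.0, 1.0])))
            continue
        fpr, tpr, _ = roc_curve(positive, scores[:, c])
        curves.append((fpr, tpr))
        aucs[c] = roc_auc_score(positive, scores[:, c])
    macro = float(np.nanmean(aucs)) if np.isfinite(aucs).any() else np.nan
    return curves, aucs, float(macro)


@dataclass
class MetricsReport:
    """Bundle of all pixel metrics for one evaluation pool."""

    pixel_accuracy: float
    per_class_accuracy: np.ndarray
    iou_per_class: np.ndarray
    mean_iou: float
    auc_per_class: np.ndarray | None = None
    auc_macro: float | None = None

    def as_dict(self) -> dict:
        d = {"pixel_accuracy": self.pixel_accuracy, "mean_iou": self.mean_iou}
        for i, name in enumerate(("background", "leaf", "panicle")):
            d[f"accuracy_{name}"] = float(self.per_class_accuracy[i])
            d[f"iou_{name}"] = float(self.iou_per_class[i])
            if self.auc_per_class is not None:
                d[f"auc_{name}"] = float(self.auc_per_class[i])
        if self.auc_macro is not None:
            d["auc_macro"] = self.auc_macro
        return d


def evaluate(preds, truths, probmaps=None) -> MetricsReport:
    """Pooled metrics over aligned lists of predicted and true masks."""
    if not isinstance(preds, (list, tuple)):
        preds, truths = [preds], [truths]
    cm = sum(confusion(p, t) for p, t in zip(preds, truths))
    report = MetricsReport(
        pixel_accuracy=pixel_accuracy(cm),
        per_class_accuracy=per_class_accuracy(cm),
        iou_per_class=iou_per_class(cm),
        mean_iou=mean_iou(cm),
    )
    if probmaps is not None:
        _, aucs, macro = roc_auc(list(probmaps), list(truths))
        report.auc_per_class = aucs
        report.auc_macro = macro
    return report
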