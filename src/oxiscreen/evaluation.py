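"""Confusion matrices and classification metrics for the screening models.

Precision, recall and F1 are reported per class and under two averaging
conventions: support-weighted (the default; its recall equals accuracy by
algebra) and macro. Binary AUC is the rank (Mann-Whitney) statistic;
multiclass AUC is macro one-vs-rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "classification_metrics",
    "f1_from_pr",
    "roc_auc",
    "evaluate",
]


@dataclass
class EvalReport:
    """Metrics of one classifier on one labelled set.

    ``confusion`` rows are truth, columns prediction, in ``classes`` order.
    """

    classes: list
    confusion: np.ndarray = field(repr=False)
    per_class: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    accuracy: float = 0.0
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "weighted": self.weighted,
            "macro": self.macro,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """K x K count matrix; entry (i, j) = truth ``classes[i]`` predicted
    ``classes[j]``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    known = set(map(str, classes))
    outside = {str(v) for v in np.concatenate([y_true, y_pred])} - known
    if outside:
        raise ValueError(f"label outside class set: {sorted(outside)}")
    return skm.confusion_matrix(y_true, y_pred, labels=list(classes))


def classification_metrics(confusion: np.ndarray, classes=None) -> EvalReport:
    """Per-class and averaged precision/recall/F1 plus accuracy from a
    confusion matrix. Empty denominators score 0."""
    cm = np.asarray(confusion, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    if classes is None:
        classes = list(range(k))
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
    f1 = np.array([f1_from_pr(p, r) for p, r in zip(precision, recall)])
    w = support / support.sum()
    per_class = {
        str(c): {"precision": float(p), "recall": float(r), "f1": float(f), "support": int(s)}
        for c, p, r, f, s in zip(classes, precision, recall, f1, support)
    }
    report = EvalReport(
        classes=list(classes),
        confusion=np.asarray(confusion),
        per_class=per_class,
        weighted={
            "precision": float(w @ precision),
            "recall": float(w @ recall),
            "f1": float(w @ f1),
        },
        macro={
            "precision": float(precision.mean()),
            "recall": float(recall.mean()),
            "f1": float(f1.mean()),
        },
        accuracy=float(tp.sum() / cm.sum()),
    )
    return report


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 by convention when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def roc_auc(y_true, scores, classes=None, pos_label=None) -> float:
    """Area under the ROC curve.

    Binary: ``scores`` are scores for ``pos_label`` (default: the larger
    label) and the AUC is the rank statistic with ties averaged.
    Multiclass: ``scores`` is an (n, K) matrix with columns in ``classes``
    order and the AUC is macro one-vs-rest.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined for single-class truth")
    if scores.ndim == 1:
        if pos_label is not None:
            y_true = (y_true == pos_label).astype(int)
        return float(skm.roc_auc_score(y_true, scores))
    if classes is None:
        classes = sorted(np.unique(y_true))
    order = sorted(range(len(classes)), key=lambda i: str(classes[i]))
    return float(
        skm.roc_auc_score(
            y_true,
            scores[:, order],
            multi_class="ovr",
            average="macro",
            labels=[classes[i] for i in order],
        )
    )


def evaluate(y_true, y_pred, classes, scores=None) -> EvalReport:
    """Confusion matrix + metrics from raw label vectors in one call."""
    cm = confusion_matrix(y_true, y_pred, classes)
    report = classification_metrics(cm, classes)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        try:
            if scores.ndim == 1:
                # convention: binary scores refer to the second listed class
                report.auc = roc_auc(y_true, scores, pos_label=list(classes)[1])
            else:
                report.auc = roc_auc(y_true, scores, classes=list(classes))
        except ValueError:
            report.auc = None
    return report
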