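"""Binary confusion-matrix metrics, ROC curves and AUC.

Scalar metrics follow the standard confusion-count definitions:
accuracy = (tp+tn)/(tp+tn+fp+fn), precision = tp/(tp+fp),
recall = tp/(tp+fn), F1 = harmonic mean of precision and recall — all
reported as percentages.  The positive class defaults to "female"
(the lines phenotype of the synthetic benchmark); it is configurable
and swapping it transposes fp/fn and tp/tn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "summarize",
    "f1_from_precision_recall",
    "roc_auc",
    "plot_confusion",
    "plot_roc",
]

DEFAULT_POSITIVE = "female"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    positive: object = DEFAULT_POSITIVE

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, positive=DEFAULT_POSITIVE) -> ConfusionCounts:
    """Exact binary confusion counts with a configurable positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if labels.size > 2:
        raise ValueError(f"labels are not binary: {labels.tolist()}")
    if positive not in labels:
        raise ValueError(f"positive class {positive!r} absent from labels {labels.tolist()}")
    tpos = y_true == positive
    ppos = y_pred == positive
    return ConfusionCounts(tp=int(np.sum(tpos & ppos)),
                           tn=int(np.sum(~tpos & ~ppos)),
                           fp=int(np.sum(~tpos & ppos)),
                           fn=int(np.sum(tpos & ~ppos)),
                           positive=positive)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean, on whatever scale (fraction or percent) the inputs use."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvalReport:
    """Scalar metrics (percent) plus per-class and macro variants."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall, "macro_f1": self.macro_f1,
                "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                           "fp": self.counts.fp, "fn": self.counts.fn}}


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0",
                      RuntimeWarning, stacklevel=3)
        prec = 0.0
    else:
        prec = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive truths; recall set to 0",
                      RuntimeWarning, stacklevel=3)
        rec = 0.0
    else:
        rec = 100.0 * tp / (tp + fn)
    return prec, rec, f1_from_precision_recall(prec, rec)


def summarize(cm: ConfusionCounts) -> EvalReport:
    """Accuracy/precision/recall/F1 (percent) from confusion counts.

    Zero-denominator precision or recall falls back to 0 with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion counts")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    p_pos, r_pos, f_pos = _prf(cm.tp, cm.fp, cm.fn)
    p_neg, r_neg, f_neg = _prf(cm.tn, cm.fn, cm.fp)  # negative class as "positive"
    per_class = {"positive": {"precision": p_pos, "recall": r_pos, "f1": f_pos},
                 "negative": {"precision": p_neg, "recall": r_neg, "f1": f_neg}}
    return EvalReport(accuracy=acc, precision=p_pos, recall=r_pos, f1=f_pos,
                      per_class=per_class,
                      macro_precision=(p_pos + p_neg) / 2,
                      macro_recall=(r_pos + r_neg) / 2,
                      macro_f1=(f_pos + f_neg) / 2, counts=cm)


def roc_auc(y_true, scores, positive=DEFAULT_POSITIVE):
    """ROC curve (threshold sweep over unique scores) and trapezoidal AUC.

    Returns ``(fpr, tpr, auc)``.  Tied scores step simultaneously.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    labels = np.unique(y_true)
    if labels.size != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, pos_label=positive)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def plot_confusion(cm: ConfusionCounts, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.array([[cm.tp, cm.fn], [cm.fp, cm.tn]])
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], [f"{cm.positive}", "other"])
    ax.set_yticks([0, 1], [f"{cm.positive}", "other"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curves: dict, path) -> None:
    """``curves`` maps a name to ``(fpr, tpr, auc)``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.6))
    for name, (fpr, tpr, auc) in curves.items():
        ax.plot(fpr, tpr, lw=1, label=f"{name} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
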