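"""Classification metrics and a rank-statistic ROC AUC.

F1 is the harmonic mean of precision and recall.  Ratios with zero
denominators are reported as NaN, never silently as 0.  Multi-class input
is reduced one-vs-rest with macro averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "classification_metrics", "roc_auc", "macro_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("labels must be equal-length nonempty 1-D arrays")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    t = t.astype(bool)
    p = p.astype(bool)
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def classification_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1 for binary labels.

    ``scores`` optionally adds the ROC AUC.  Undefined ratios are NaN.
    """
    c = confusion_counts(y_true, y_pred)
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    auc = None
    if scores is not None:
        auc = roc_auc(scores, y_true)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_ratio(c.tn, c.tn + c.fp),
        auc=auc,
    )


def roc_auc(scores, y_true) -> float:
    """P(random positive outranks random negative), ties counted 1/2.

    Equals the normalized Mann-Whitney U statistic.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y_true)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    pos = t.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_metrics(y_true, y_pred) -> MetricsReport:
    """One-vs-rest macro average over the classes present in y_true."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    classes = np.unique(t)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    reports = [classification_metrics((t == c).astype(int), (p == c).astype(int)) for c in classes]

    def avg(attr: str) -> float:
        vals = [getattr(r, attr) for r in reports]
        return float(np.nanmean(vals))

    return MetricsReport(
        accuracy=avg("accuracy"),
        precision=avg("precision"),
        recall=avg("recall"),
        f1=avg("f1"),
        specificity=avg("specificity"),
    )
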