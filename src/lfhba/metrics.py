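"""Classification metrics, Friedman mean ranks, and score-table aggregation.

Implements the five confusion-matrix metrics used to compare feature
selectors (precision, recall, F1, accuracy, balanced accuracy), one-vs-rest
multi-class averaging, the Friedman mean-rank aggregation used for
nonparametric method comparison across dataset/model blocks, and simple
column-group averaging of score tables.

Zero-denominator ratios return 0 by convention, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "multiclass_metrics",
    "friedman_mean_ranks",
    "aggregate_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    balanced_accuracy: float

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning 0")
        return 0.0
    return num / den


def confusion_counts(y_true, y_pred, positive_label) -> ConfusionCounts:
    """Tally the 2x2 confusion table against one positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision, recall, F1, accuracy and balanced accuracy from counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2*precision*recall/(precision+recall);
    accuracy = (TP+TN)/n;
    balanced accuracy = (TP/(TP+FN) + TN/(FP+TN)) / 2.
    """
    if counts.total < 1:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "F1")
    accuracy = (tp + tn) / counts.total
    specificity = _ratio(tn, fp + tn, "specificity")
    balanced = 0.5 * (recall + specificity)
    return MetricsReport(precision, recall, f1, accuracy, balanced)


def multiclass_metrics(
    y_true,
    y_pred,
    classes=None,
    averaging: str = "weighted",
) -> MetricsReport:
    """One-vs-rest metrics combined across classes.

    ``averaging`` is "weighted" (by class support; default) or "macro".
    Accuracy is the plain overall agreement; balanced accuracy is the mean
    per-class recall, matching its binary definition at two classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    unknown = np.setdiff1d(np.union1d(np.unique(y_true), np.unique(y_pred)), classes)
    if unknown.size:
        raise ValueError(f"labels outside the declared classes: {unknown.tolist()}")
    if averaging not in ("macro", "weighted"):
        raise ValueError(f"unknown averaging {averaging!r}")

    reports = [compute_metrics(confusion_counts(y_true, y_pred, c)) for c in classes]
    support = np.array([np.sum(y_true == c) for c in classes], dtype=float)
    if averaging == "weighted":
        w = support / support.sum()
    else:
        w = np.full(classes.size, 1.0 / classes.size)

    precision = float(sum(wi * r.precision for wi, r in zip(w, reports)))
    recall = float(sum(wi * r.recall for wi, r in zip(w, reports)))
    f1 = float(sum(wi * r.f1 for wi, r in zip(w, reports)))
    accuracy = float(np.mean(y_true == y_pred))
    balanced = float(np.mean([r.recall for r in reports]))
    return MetricsReport(precision, recall, f1, accuracy, balanced)


def friedman_mean_ranks(
    table: pd.DataFrame,
    higher_is_better: bool = True,
) -> pd.Series:
    """Friedman mean ranks of methods (rows) over blocks (columns).

    Within each block the k methods are ranked; ties receive averaged
    ranks.  Under ``higher_is_better`` the best method gets rank k (so a
    larger mean rank is better), matching the convention of reporting the
    winner with the highest mean ranking.  Returns the per-method mean over
    blocks, which always sums to k(k+1)/2.
    """
    if table.shape[0] < 2 or table.shape[1] < 1:
        raise ValueError("need >= 2 methods and >= 1 block")
    if table.isna().any().any():
        raise ValueError("score table has missing cells")
    values = table.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, values)  # 1 = smallest score
    if not higher_is_better:
        ranks = table.shape[0] + 1 - ranks
    return pd.Series(ranks.mean(axis=1), index=table.index, name="mean_rank")


def aggregate_table(table: pd.DataFrame, group: list | None = None) -> pd.Series:
    """Per-method arithmetic mean over a group of block columns, to 2 decimals."""
    if group is None:
        group = list(table.columns)
    if len(group) == 0:
        raise ValueError("group must be non-empty")
    missing = [g for g in group if g not in table.columns]
    if missing:
        raise KeyError(f"unknown block columns: {missing}")
    return table[group].mean(axis=1).round(2)
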