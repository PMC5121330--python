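"""Threshold metrics, precision-recall and ROC curves.

A score is called positive when it is strictly above the cutoff.  All
ratio metrics return 0 on a 0/0 denominator (including the MCC), a
documented convention for degenerate confusion tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("negative confusion count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    specificity: float
    fpr: float
    acc: float
    mcc: float


@dataclass
class Curve:
    kind: str                  # "PRC" or "ROC"
    cutoffs: np.ndarray        # strictly decreasing
    x: np.ndarray              # recall (PRC) or FPR (ROC)
    y: np.ndarray              # precision (PRC) or TPR (ROC)

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.cutoffs) == len(self.x) == len(self.y)):
            raise ValueError("curve arrays must share a length")
        if np.any(np.diff(self.cutoffs) >= 0):
            raise ValueError("curve cutoffs must be strictly decreasing")


def _check_pairs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equally long")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return s, y


def confusion(scores, labels, cutoff: float) -> ConfusionCounts:
    """Confusion counts at a cutoff; predicted positive iff score > cutoff."""
    s, y = _check_pairs(scores, labels)
    pred = s > cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def metric_set(c: ConfusionCounts) -> MetricSet:
    """precision, recall (= sensitivity/TPR), specificity, FPR, accuracy and
    Matthews correlation coefficient from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    return MetricSet(
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        fpr=_ratio(c.fp, c.fp + c.tn),
        acc=_ratio(c.tp + c.tn, c.total),
        mcc=_ratio(c.tp * c.tn - c.fp * c.fn, mcc_den),
    )


def _cumulative(scores: np.ndarray, labels: np.ndarray):
    """TP/FP counts at every distinct-score cutoff, descending.

    Returns (cutoffs, tp, fp) where entry i gives the counts for
    predicted-positive = score > cutoffs[i]; a final -inf cutoff predicts
    everything positive.
    """
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    first = np.r_[True, s[1:] != s[:-1]]
    firsts = np.where(first)[0]
    cutoffs = np.r_[s[firsts], -np.inf]
    tp = np.r_[0, tp_cum[firsts[1:] - 1], tp_cum[-1]] if len(firsts) > 1 \
        else np.r_[0, tp_cum[-1]]
    fp = np.r_[0, fp_cum[firsts[1:] - 1], fp_cum[-1]] if len(firsts) > 1 \
        else np.r_[0, fp_cum[-1]]
    return cutoffs, tp, fp


def roc_curve(scores, labels) -> Curve:
    """ROC curve (FPR, TPR) with one point per distinct-score cutoff, from
    (0,0) at the highest cutoff to (1,1) when everything is called positive."""
    s, y = _check_pairs(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    cutoffs, tp, fp = _cumulative(s, y)
    return Curve(kind="ROC", cutoffs=cutoffs, x=fp / n_neg, y=tp / n_pos)


def pr_curve(scores, labels) -> Curve:
    """Precision-recall curve with one point per cutoff that predicts at
    least one positive, anchored at recall 0 with the first point's
    precision (constant extension, so tied top scores still span the
    low-recall end)."""
    s, y = _check_pairs(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("PRC needs at least one positive and one negative")
    cutoffs, tp, fp = _cumulative(s, y)
    keep = (tp + fp) > 0
    tp, fp, cutoffs = tp[keep], fp[keep], cutoffs[keep]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    if recall[0] > 0:
        cutoffs = np.r_[np.inf, cutoffs]
        recall = np.r_[0.0, recall]
        precision = np.r_[precision[0], precision]
    return Curve(kind="PRC", cutoffs=cutoffs, x=recall, y=precision)


def auc(curve: Curve) -> float:
    """Trapezoidal area under the x-sorted curve."""
    if len(curve.x) < 2:
        raise ValueError("AUC needs at least two curve points")
    order = np.argsort(curve.x, kind="stable")
    return float(np.trapezoid(curve.y[order], curve.x[order]))


def random_baseline(labels) -> float:
    """Expected precision of a random guess: fraction of positives."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty label vector")
    return float(y.mean())


def metrics_table(scores, labels, cutoffs) -> "pd.DataFrame":  # noqa: F821
    """Per-cutoff metric table (one row per cutoff) for reports."""
    import pandas as pd

    rows = []
    for t in cutoffs:
        c = confusion(scores, labels, t)
        m = metric_set(c)
        rows.append({
            "cutoff": t, "TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn,
            "precision": m.precision, "recall": m.recall,
            "specificity": m.specificity, "FPR": m.fpr,
            "ACC": m.acc, "MCC": m.mcc,
        })
    return pd.DataFrame(rows)
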