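"""Confusion-matrix metrics, ROC/AUC, and report assembly.

OA is the positive class throughout.  Reports also carry the HC-positive
orientation of sensitivity/specificity/precision because published summary
tables for this protocol mix the two conventions; F1 for the OA-positive
orientation and MCC (orientation-symmetric) anchor comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

POSITIVE_LABEL = "OA"
NEGATIVE_LABEL = "HC"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    counts: dict
    hc_total: int
    hc_correct: int
    hc_correct_pct: float
    oa_total: int
    oa_correct: int
    oa_correct_pct: float
    accuracy_pct: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    mcc: float | None
    # HC-positive orientation of the asymmetric rates
    sensitivity_hc_positive: float | None = None
    specificity_hc_positive: float | None = None
    precision_hc_positive: float | None = None
    undefined: list[str] = field(default_factory=list)
    roc: list[list[float]] = field(default_factory=list)   # (fpr, tpr, threshold)
    auc: float | None = None
    roc_threshold: float | None = None


def _norm_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    out = np.empty(arr.size, dtype=int)
    for i, v in enumerate(arr.ravel()):
        s = getattr(v, "value", v)
        if s == POSITIVE_LABEL:
            out[i] = 1
        elif s == NEGATIVE_LABEL:
            out[i] = 0
        else:
            raise ValueError(f"unknown label {v!r}")
    return out


def confusion(labels, predictions) -> ConfusionCounts:
    y = _norm_labels(labels)
    p = _norm_labels(predictions)
    if y.size != p.size:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float | None:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def metrics(c: ConfusionCounts) -> EvaluationReport:
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    und: list[str] = []
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", und)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", und)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", und)
    if prec is None or sens is None or (prec + sens) == 0:
        und.append("f1")
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        und.append("mcc")
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return EvaluationReport(
        counts={"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
        hc_total=c.tn + c.fp, hc_correct=c.tn,
        hc_correct_pct=100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan"),
        oa_total=c.tp + c.fn, oa_correct=c.tp,
        oa_correct_pct=100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan"),
        accuracy_pct=100.0 * (c.tp + c.tn) / c.total,
        sensitivity=sens, specificity=spec, precision=prec, recall=sens,
        f1=f1, mcc=mcc,
        sensitivity_hc_positive=_ratio(c.tn, c.tn + c.fp, "sensitivity_hc", und),
        specificity_hc_positive=_ratio(c.tp, c.tp + c.fn, "specificity_hc", und),
        precision_hc_positive=_ratio(c.tn, c.tn + c.fn, "precision_hc", und),
        undefined=und,
    )


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """Threshold sweep over the unique OA-probability scores.

    A case is called OA when score >= threshold.  The list runs from (0, 0)
    at threshold +inf to (1, 1) at the smallest score and is monotone in
    both coordinates.
    """
    s = np.asarray(scores, dtype=float)
    y = _norm_labels(labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    points = [(0.0, 0.0, float("inf"))]
    for thr in np.unique(s)[::-1]:
        called = s >= thr
        tpr = float(np.sum(called & (y == 1))) / n_pos
        fpr = float(np.sum(called & (y == 0))) / n_neg
        points.append((fpr, tpr, float(thr)))
    if points[-1][:2] != (1.0, 1.0):
        points.append((1.0, 1.0, float(np.min(s))))
    return points


def auc(roc: list[tuple[float, float, float]]) -> float:
    """Trapezoidal area under the ROC curve."""
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    return float(np.trapezoid(tpr, fpr))


def operating_threshold(roc: list[tuple[float, float, float]]) -> float:
    """Threshold maximizing Youden's J = TPR - FPR; ties go to the larger
    threshold."""
    best_j, best_thr = -np.inf, None
    for fpr, tpr, thr in roc:
        if not np.isfinite(thr):
            continue
        j = tpr - fpr
        if j > best_j or (j == best_j and thr > best_thr):
            best_j, best_thr = j, thr
    return float(best_thr)


def evaluate(labels, scores, threshold: float = 0.5) -> EvaluationReport:
    """Full report: confusion at ``threshold`` plus ROC curve, AUC and the
    Youden operating point."""
    y = _norm_labels(labels)
    s = np.asarray(scores, dtype=float)
    preds = (s >= threshold).astype(int)
    rep = metrics(confusion(y, preds))
    pts = roc_points(s, y)
    rep.roc = [list(p) for p in pts]
    rep.auc = auc(pts)
    rep.roc_threshold = operating_threshold(pts)
    return rep
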