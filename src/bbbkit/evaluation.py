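"""Binary-classification performance metrics.

Confusion counts, the standard derived metrics (sensitivity, specificity,
accuracy, balanced accuracy, precision, F1, Matthews correlation, Cohen's
kappa) and ROC-AUC computed by an explicit threshold sweep.

Metrics that are mathematically undefined for a given confusion matrix
(division by a zero margin) are reported as ``nan`` together with an entry in
:attr:`MetricsReport.undefined` naming the offending margin — never silently
coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .exceptions import InputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion matrix: positives are the active (BBB+) class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    precision: float
    f1: float
    mcc: float
    kappa: float
    counts: ConfusionCounts
    roc_auc: float = math.nan
    undefined: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "roc_auc": self.roc_auc,
            "counts": {
                "tp": self.counts.tp,
                "fn": self.counts.fn,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
            },
            "undefined": dict(self.undefined),
        }
        return d

    def to_json(self, **kwargs) -> str:
        def _clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        d = self.to_dict()
        d = {k: (_clean(v) if not isinstance(v, dict) else v) for k, v in d.items()}
        return json.dumps(d, indent=2, **kwargs)


def _as_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.size == 0:
        raise InputError(f"{name} is empty")
    vals = set(np.unique(arr).tolist())
    if not vals <= {0, 1, False, True}:
        raise InputError(f"{name} must be binary 0/1, got values {sorted(vals)}")
    return arr.astype(int)


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Count tp/fn/fp/tn from parallel label sequences (1 = active)."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise InputError(f"length mismatch: {t.shape} vs {p.shape}")
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate every confusion-derived metric for ``counts``.

    Undefined values (zero denominators) become ``nan`` with a reason in the
    report's ``undefined`` mapping.
    """
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    n = counts.total
    undefined: Dict[str, str] = {}

    def ratio(num, den, metric, margin):
        if den == 0:
            undefined[metric] = f"zero margin: {margin}"
            return math.nan
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity", "no positive samples (TP+FN=0)")
    spec = ratio(tn, tn + fp, "specificity", "no negative samples (TN+FP=0)")
    acc = ratio(tp + tn, n, "accuracy", "empty confusion matrix")
    if math.isnan(sens) or math.isnan(spec):
        undefined["balanced_accuracy"] = "sensitivity or specificity undefined"
        bacc = math.nan
    else:
        bacc = (sens + spec) / 2.0
    prec = ratio(tp, tp + fp, "precision", "no positive predictions (TP+FP=0)")
    if math.isnan(prec) or math.isnan(sens):
        undefined["f1"] = "precision or sensitivity undefined"
        f1 = math.nan
    elif prec + sens == 0:
        undefined["f1"] = "precision + sensitivity = 0"
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)

    mcc_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den_sq == 0:
        zero = [
            m
            for m, v in [
                ("TP+FP", tp + fp),
                ("TP+FN", tp + fn),
                ("TN+FP", tn + fp),
                ("TN+FN", tn + fn),
            ]
            if v == 0
        ]
        undefined["mcc"] = f"zero margin(s): {', '.join(zero)}"
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den_sq)

    # Cohen's kappa: chance agreement from the marginal products.
    if n == 0:
        undefined["kappa"] = "empty confusion matrix"
        kappa = math.nan
    else:
        pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
        if pe == 1.0:
            undefined["kappa"] = "chance agreement P_e = 1 (degenerate marginals)"
            kappa = math.nan
        else:
            kappa = (acc - pe) / (1.0 - pe)

    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=bacc,
        precision=prec,
        f1=f1,
        mcc=mcc,
        kappa=kappa,
        counts=counts,
        undefined=undefined,
    )


def roc_auc(y_true: Sequence, probabilities: Sequence[float]) -> float:
    """Area under the ROC curve via a threshold sweep over sorted scores.

    Tied scores are processed as a single threshold step, which makes the
    result identical to the pairwise rank formulation with ties counted 1/2.

    Raises
    ------
    UndefinedMetricError
        If only one class is present in ``y_true``.
    """
    t = _as_binary(y_true, "y_true")
    p = np.asarray(probabilities, dtype=float)
    if t.shape != p.shape:
        raise InputError(f"length mismatch: {t.shape} vs {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InputError("probabilities must be finite")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "roc_auc", "only one class present in y_true"
        )
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    t_sorted = t[order]
    # Cumulative TP/FP at each distinct-threshold boundary.
    distinct = np.r_[np.diff(p_sorted) != 0, True]
    tps = np.cumsum(t_sorted)[distinct]
    fps = np.cumsum(1 - t_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))
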