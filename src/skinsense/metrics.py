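"""Binary-classification performance measures.

Eight measures are reported throughout the package: Matthews correlation
coefficient (MCC), accuracy (ACC), area under the ROC curve (AUC),
sensitivity (Se), specificity (Sp), positive/negative predictive value
(PPV/NPV) and the correct classification rate (CCR), defined as the
arithmetic mean of Se and Sp.

Conventions for degenerate inputs: the MCC is defined as 0 whenever any
factor of its denominator is 0; ratios with a zero denominator (e.g. PPV
with no positive predictions) are reported as NaN and listed in
``MetricsBundle.undefined`` rather than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsBundle",
    "confusion",
    "mcc",
    "acc",
    "se",
    "sp",
    "ppv",
    "npv",
    "ccr",
    "auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of true/false positive/negative predictions."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, predictions, positive=1) -> ConfusionCounts:
    """Tabulate confusion counts for binary labels and predictions."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {predictions.shape} predictions"
        )
    y = labels == positive
    p = predictions == positive
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        tn=int(np.sum(~y & ~p)),
        fn=int(np.sum(y & ~p)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def acc(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.total


def se(c: ConfusionCounts) -> float:
    """Sensitivity: fraction of actual positives predicted positive."""
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan


def sp(c: ConfusionCounts) -> float:
    """Specificity: fraction of actual negatives predicted negative."""
    return c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan


def ppv(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else math.nan


def npv(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fn) if (c.tn + c.fn) > 0 else math.nan


def ccr(se_value: float, sp_value: float) -> float:
    """Correct classification rate: the mean of sensitivity and specificity."""
    return (se_value + sp_value) / 2.0


def auc(labels, scores, positive=1) -> float:
    """Area under the ROC curve (Mann-Whitney rank statistic, ties half).

    Raises ``ValueError`` if only one class is present.
    """
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class MetricsBundle:
    """The eight performance measures, with NaN + flag for undefined ratios."""

    mcc: float
    acc: float
    auc: float
    se: float
    sp: float
    ppv: float
    npv: float
    ccr: float
    n: int = 0
    undefined: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_counts(cls, c: ConfusionCounts, auc_value: float = math.nan) -> "MetricsBundle":
        se_v, sp_v, ppv_v, npv_v = se(c), sp(c), ppv(c), npv(c)
        vals = {"se": se_v, "sp": sp_v, "ppv": ppv_v, "npv": npv_v}
        ccr_v = ccr(se_v, sp_v)
        if math.isnan(ccr_v):
            vals["ccr"] = ccr_v
        if math.isnan(auc_value):
            vals["auc"] = auc_value
        undef = frozenset(k for k, v in vals.items() if isinstance(v, float) and math.isnan(v))
        return cls(
            mcc=mcc(c),
            acc=acc(c),
            auc=auc_value,
            se=se_v,
            sp=sp_v,
            ppv=ppv_v,
            npv=npv_v,
            ccr=ccr_v,
            n=c.total,
            undefined=undef,
        )

    @classmethod
    def from_predictions(cls, labels, predictions, scores=None, positive=1) -> "MetricsBundle":
        c = confusion(labels, predictions, positive=positive)
        auc_value = math.nan
        if scores is not None:
            y = np.asarray(labels) == positive
            if y.min() != y.max():
                auc_value = auc(labels, scores, positive=positive)
        return cls.from_counts(c, auc_value)

    def to_dict(self) -> dict:
        return {
            "MCC": self.mcc,
            "ACC": self.acc,
            "AUC": self.auc,
            "Se": self.se,
            "Sp": self.sp,
            "PPV": self.ppv,
            "NPV": self.npv,
            "CCR": self.ccr,
            "n": self.n,
        }
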