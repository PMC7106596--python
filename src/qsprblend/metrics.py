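"""Evaluation statistics for QSPR regression and binary classification.

Regression models are scored with the root mean square error (RMSE, in the
units of the target, e.g. nm for emission wavelengths) and the coefficient of
determination R². Binary classifiers are scored from the confusion table
(a = true positives, b = false negatives, c = false positives,
d = true negatives) with accuracy, precision, recall, F1 and the Matthews
correlation coefficient (MCC), the latter two being the statistics of choice
under class imbalance such as the ~73/27 liquid-crystal / non-liquid-crystal
split these models are built for.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "ConfusionTable",
    "MetricReport",
    "rmse",
    "r_squared",
    "confusion_table",
    "classification_metrics",
    "regression_metrics",
    "format_percent",
]


def format_percent(value: float, decimals: int = 1) -> str:
    """Format a fraction as a percentage, rounding half-up.

    Half-up (not banker's) rounding matches how results tables in the
    QSPR literature are conventionally printed: 0.88384 -> "88.4".
    """
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """Binary confusion counts: a=TP, b=FN, c=FP, d=TN."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("confusion counts must be nonnegative integers")
        if sum(counts) < 1:
            raise ValueError("confusion table must contain at least one sample")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_matrix(self) -> np.ndarray:
        """2x2 array, rows = actual (pos, neg), cols = predicted (pos, neg)."""
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def __str__(self) -> str:  # printed in the conventional 2x2 layout
        w = max(len(str(x)) for x in (self.a, self.b, self.c, self.d))
        return (
            f"actual\\pred  {'pos':>{w + 3}}  {'neg':>{w + 3}}\n"
            f"pos          {self.a:>{w + 3}}  {self.b:>{w + 3}}\n"
            f"neg          {self.c:>{w + 3}}  {self.d:>{w + 3}}"
        )


@dataclass
class MetricReport:
    """Container for either the regression or the classification statistics.

    Classification fractions are stored at full precision; use
    :meth:`as_percent` / :func:`format_percent` for table-style display.
    ``undefined`` lists statistics whose denominator was zero.
    """

    task: str
    rmse: float | None = None
    r_squared: float | None = None
    acc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    mcc: float | None = None
    confusion: ConfusionTable | None = None
    undefined: list[str] = field(default_factory=list)

    def as_percent(self, decimals: int = 1) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in ("acc", "precision", "recall", "f1", "mcc"):
            value = getattr(self, name)
            if value is not None:
                out[name] = format_percent(value, decimals)
        return out

    def to_json(self) -> str:
        payload: dict = {"task": self.task}
        for name in ("rmse", "r_squared", "acc", "precision", "recall", "f1", "mcc"):
            value = getattr(self, name)
            if value is not None:
                payload[name] = value
        if self.confusion is not None:
            payload["confusion"] = {
                "a": self.confusion.a,
                "b": self.confusion.b,
                "c": self.confusion.c,
                "d": self.confusion.d,
            }
        if self.undefined:
            payload["undefined"] = self.undefined
        return json.dumps(payload, indent=2)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def rmse(observed, predicted) -> float:
    """Root mean square error sqrt(mean((y - yhat)^2))."""
    obs = _as_1d(observed, "observed")
    pred = _as_1d(predicted, "predicted")
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: observed has {obs.size}, predicted has {pred.size}"
        )
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of *observed* — for a held-out test set
    this is the test-set mean (the dominant convention for predictive R²).
    """
    obs = _as_1d(observed, "observed")
    pred = _as_1d(predicted, "predicted")
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: observed has {obs.size}, predicted has {pred.size}"
        )
    if obs.size < 2:
        raise ValueError("r_squared requires at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed vector is constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def confusion_table(true_labels, predicted_labels, positive_label) -> ConfusionTable:
    """Tally the binary confusion counts with ``positive_label`` as positive."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = set(np.unique(y_true).tolist()) | set(np.unique(y_pred).tolist())
    if len(classes) > 2:
        raise ValueError(f"more than two classes present: {sorted(map(str, classes))}")
    tp = (y_true == positive_label) & (y_pred == positive_label)
    fn = (y_true == positive_label) & (y_pred != positive_label)
    fp = (y_true != positive_label) & (y_pred == positive_label)
    tn = (y_true != positive_label) & (y_pred != positive_label)
    return ConfusionTable(
        a=int(tp.sum()), b=int(fn.sum()), c=int(fp.sum()), d=int(tn.sum())
    )


def classification_metrics(ct: ConfusionTable) -> MetricReport:
    """Acc, Pr, r, F1 and MCC from the confusion counts.

    Acc = (a+d)/(a+b+c+d); Pr = a/(a+c); r = a/(a+b); F1 = 2a/(2a+b+c);
    MCC = (ad - bc) / sqrt((a+b)(a+c)(b+d)(c+d)).

    A zero MCC denominator yields MCC = 0 (the standard convention); a zero
    denominator for Pr, r or F1 leaves that statistic as None and records it
    in ``undefined``.
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    undefined: list[str] = []

    acc = (a + d) / ct.total

    precision = a / (a + c) if (a + c) > 0 else None
    if precision is None:
        undefined.append("precision")
    recall = a / (a + b) if (a + b) > 0 else None
    if recall is None:
        undefined.append("recall")
    f1 = 2 * a / (2 * a + b + c) if (2 * a + b + c) > 0 else None
    if f1 is None:
        undefined.append("f1")

    denom = math.sqrt((a + b) * (a + c) * (b + d) * (c + d))
    if denom == 0.0:
        warnings.warn("MCC denominator is zero; returning 0 by convention")
        mcc = 0.0
        undefined.append("mcc")
    else:
        mcc = (a * d - b * c) / denom

    return MetricReport(
        task="classification",
        acc=acc,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        confusion=ct,
        undefined=undefined,
    )


def regression_metrics(observed, predicted) -> MetricReport:
    """RMSE and R² in one report."""
    return MetricReport(
        task="regression",
        rmse=rmse(observed, predicted),
        r_squared=r_squared(observed, predicted),
    )
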