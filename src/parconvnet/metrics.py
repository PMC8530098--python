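"""Confusion-count bookkeeping and the five evaluation metrics.

Accuracy, specificity, recall (sensitivity), precision and F1 are computed
from TP/TN/FP/FN on the percentage scale:

    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
    specificity = 100 * TN / (FP + TN)
    recall      = 100 * TP / (TP + FN)
    precision   = 100 * TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

Zero-denominator submetrics are reported as undefined (``None`` plus a flag)
rather than coerced to 0 or 100.  Multiclass problems use macro-averaged
one-vs-rest counts with the per-class breakdown retained.  Values are carried
at full precision; rounding to one decimal happens only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "f1_from_pr",
    "multiclass_metrics",
]

METRIC_ORDER = ("accuracy", "specificity", "recall", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """The five metrics as percentages; ``None`` marks an undefined metric.

    ``undefined`` lists which metrics had a zero denominator.  ``per_class``
    holds the one-vs-rest breakdown for multiclass evaluations.
    """

    accuracy: float | None
    specificity: float | None
    recall: float | None
    precision: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()
    per_class: dict[str, "MetricsReport"] = field(default_factory=dict)

    def as_dict(self, ndigits: int | None = 1) -> dict:
        def fmt(v):
            if v is None:
                return None
            return round(v, ndigits) if ndigits is not None else v

        out = {m: fmt(getattr(self, m)) for m in METRIC_ORDER}
        if self.undefined:
            out["undefined"] = list(self.undefined)
        if self.per_class:
            out["per_class"] = {
                k: v.as_dict(ndigits) for k, v in self.per_class.items()
            }
        return out

    def to_csv_row(self, ndigits: int = 1) -> str:
        """One CSV row in table column order (accuracy ... F1-score)."""
        header = "Accuracy,Specificity,Recall,Precision,F1-Score"
        vals = ",".join(
            "" if getattr(self, m) is None else f"{round(getattr(self, m), ndigits)}"
            for m in METRIC_ORDER
        )
        return f"{header}\n{vals}\n"


def confusion_counts(y_true, y_pred, positive_label) -> ConfusionCounts:
    """TP/TN/FP/FN with respect to one positive label.

    TP and TN count correctly classified positive and negative instances;
    FN and FP count misclassified positive and negative instances.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if y_true and positive_label not in set(y_true) | set(y_pred):
        raise ValueError(f"positive label {positive_label!r} absent from labels")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five metrics from one confusion table (percentages)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = 100.0 * (tp + tn) / counts.total
    specificity = _ratio(tn, fp + tn)
    recall = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = f1_from_pr(precision, recall)
    undefined = tuple(
        name
        for name, v in zip(
            ("specificity", "recall", "precision", "f1"),
            (specificity, recall, precision, f1),
        )
        if v is None
    )
    return MetricsReport(accuracy, specificity, recall, precision, f1, undefined)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall on the percentage scale.

    Full precision is kept; round only when presenting (the tables print
    one decimal).
    """
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError("precision and recall must be percentages in [0, 100]")
    if precision == 0 and recall == 0:
        raise ValueError("F1 undefined when precision and recall are both 0")
    return 2.0 * precision * recall / (precision + recall)


def multiclass_metrics(y_true, y_pred, classes=None) -> MetricsReport:
    """Macro-averaged one-vs-rest metrics with per-class breakdown.

    Each class is treated in turn as the positive label, yielding one
    confusion table per class; the report's scalars are unweighted means of
    the per-class values (classes whose metric is undefined are skipped in
    that metric's mean).  With exactly one requested class this reduces to
    :func:`compute_metrics` on that class.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if classes is None:
        classes = sorted(set(y_true))
    if not classes:
        raise ValueError("no classes to evaluate")
    per_class = {
        c: compute_metrics(confusion_counts(y_true, y_pred, c)) for c in classes
    }
    if len(per_class) == 1:
        (only,) = per_class.values()
        return MetricsReport(
            only.accuracy, only.specificity, only.recall, only.precision,
            only.f1, only.undefined, per_class=dict(per_class),
        )

    def macro(name):
        vals = [getattr(r, name) for r in per_class.values()
                if getattr(r, name) is not None]
        return float(np.mean(vals)) if vals else None

    scalars = {m: macro(m) for m in METRIC_ORDER}
    undefined = tuple(m for m in METRIC_ORDER if scalars[m] is None)
    return MetricsReport(**scalars, undefined=undefined, per_class=per_class)
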