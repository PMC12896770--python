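"""Classification metrics, subject-level aggregation and report tables.

PD is the positive class throughout.  Segment-level class probabilities
are averaged per subject and thresholded at 0.5 (ties decide PD, the
clinically conservative direction), so every reported metric is a
subject-level quantity: a 20 PD / 20 HC evaluation set can only produce
specificities that are multiples of 1/20, which is how published
independent-test rows such as specificity 0.15 (= 3/20) arise.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, MetricError

POSITIVE_LABEL = "PD"
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with PD as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        """Counts from label sequences; entries may be 'PD'/'HC' or 1/0."""
        def as01(v):
            return np.asarray([1 if y in (1, POSITIVE_LABEL) else 0 for y in v])
        t, p = as01(y_true), as01(y_pred)
        if len(t) != len(p):
            raise DataError("y_true and y_pred lengths differ")
        return cls(tp=int(np.sum((t == 1) & (p == 1))),
                   fp=int(np.sum((t == 0) & (p == 1))),
                   tn=int(np.sum((t == 0) & (p == 0))),
                   fn=int(np.sum((t == 1) & (p == 0))))


def confusion_to_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, F1) of a confusion matrix."""
    if cm.tp + cm.fn == 0:
        raise MetricError("sensitivity undefined: no positive (PD) subjects")
    if cm.tn + cm.fp == 0:
        raise MetricError("specificity undefined: no negative (HC) subjects")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn)
    specificity = cm.tn / (cm.tn + cm.fp)
    f1 = 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn)
    return accuracy, sensitivity, specificity, f1


def implied_confusion(sensitivity: float, specificity: float,
                      n_pos: int, n_neg: int) -> ConfusionMatrix:
    """The integer confusion matrix implied by rounded sensitivity/specificity.

    Inverts 2-decimal published rates on a known evaluation-set layout
    (e.g. 20 PD / 20 HC); raises if no integer matrix reproduces the
    given rates after rounding back.
    """
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    _, sens, spec, _ = confusion_to_metrics(cm)
    if round_half_up(sens) != round_half_up(sensitivity) or \
       round_half_up(spec) != round_half_up(specificity):
        raise MetricError(
            f"no integer confusion matrix on {n_pos}/{n_neg} reproduces "
            f"sensitivity={sensitivity}, specificity={specificity}")
    return cm


def aggregate_to_subject(segment_probs: dict[str, "np.ndarray | list[float]"]
                         ) -> dict[str, tuple[float, str]]:
    """Per-subject PD probability (mean of segments) and decision.

    Decision is PD iff the mean PD probability is >= 0.5.
    """
    out = {}
    for subject, probs in segment_probs.items():
        probs = np.asarray(probs, dtype=float)
        if probs.size == 0:
            raise DataError(f"subject {subject} has no segments")
        p = float(probs.mean())
        out[subject] = (p, POSITIVE_LABEL if p >= 0.5 else "HC")
    return out


def summarize_folds(per_fold: list[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Across-fold mean and sample (n-1) standard deviation per metric."""
    if len(per_fold) < 2:
        raise DataError("need at least two folds to summarize")
    out = {}
    for name in per_fold[0]:
        vals = np.asarray([f[name] for f in per_fold], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


@dataclass
class EvalResult:
    """Metrics of one (strategy, method) cell."""

    strategy: str
    method: str
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: ConfusionMatrix | None = None
    fold_summary: dict[str, tuple[float, float]] | None = None
    extra: dict = field(default_factory=dict)

    def metrics(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as in printed tables (0.575 -> 0.58).

    Decimal-based so short decimal fractions round by their printed
    value, not their binary representation.
    """
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def render_report(results: list[EvalResult]) -> pd.DataFrame:
    """One row per (strategy, method), metrics rounded half-up to 2 decimals.

    When fold summaries are present the metric columns show
    "mean ± std"; otherwise the plain rounded value.
    """
    rows = []
    for r in results:
        row = {"strategy": r.strategy, "method": r.method}
        for name in METRIC_NAMES:
            if r.fold_summary and name in r.fold_summary:
                m, s = r.fold_summary[name]
                row[name] = f"{round_half_up(m):.2f} ± {round_half_up(s):.2f}"
            else:
                row[name] = f"{round_half_up(getattr(r, name)):.2f}"
        rows.append(row)
    return pd.DataFrame(rows, columns=["strategy", "method", *METRIC_NAMES])
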