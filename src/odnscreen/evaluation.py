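"""Confusion-matrix classification metrics and their aggregation.

High-activity is the positive class. Metrics: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), balanced accuracy (Se+Sp)/2, Matthews correlation
coefficient, and precision TP/(TP+FP). A metric whose denominator is zero
is flagged as undefined (None) rather than silently coerced to 0 or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .records import HIGH, LOW


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """Metric values; None marks a metric undefined on this matrix, with
    the offending denominators listed in ``undefined``."""

    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    mcc: float | None
    precision: float | None
    undefined: tuple[str, ...] = ()


def confusion(
    predicted: Sequence[str], true: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix from high/low label vectors."""
    if len(predicted) != len(true):
        raise ValueError("predicted and true label vectors differ in length")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, true):
        if p not in (HIGH, LOW) or t not in (HIGH, LOW):
            raise ValueError(f"unknown label in pair ({p!r}, {t!r})")
        if t == HIGH:
            if p == HIGH:
                tp += 1
            else:
                fn += 1
        else:
            if p == HIGH:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy as the mean of the two per-class recalls."""
    return (sensitivity + specificity) / 2


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Compute the five metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(f"{name}: zero denominator")
            return None
        return num / den

    se = ratio(cm.TP, cm.TP + cm.FN, "sensitivity")
    sp = ratio(cm.TN, cm.TN + cm.FP, "specificity")
    ba = balanced_accuracy_from_rates(se, sp) if se is not None and sp is not None else None
    if ba is None and "sensitivity" not in " ".join(undefined):
        undefined.append("balanced_accuracy: from undefined recall")
    prec = ratio(cm.TP, cm.TP + cm.FP, "precision")
    denom = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if denom == 0:
        undefined.append("mcc: zero denominator")
        mcc = None
    else:
        mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / math.sqrt(denom)
    return MetricSet(
        sensitivity=se,
        specificity=sp,
        balanced_accuracy=ba,
        mcc=mcc,
        precision=prec,
        undefined=tuple(undefined),
    )


def format_percent(value: float) -> str:
    """Render a fraction as a percentage with 1 decimal, half-up rounding
    (0.7965 → '79.7%')."""
    pct = Decimal(str(value)) * Decimal(100)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def format_mcc(value: float) -> str:
    return str(Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Summarise per-repeat metrics into a benchmark table.

    ``results`` needs columns family, k, balanced_accuracy, mcc (one row per
    repeat). Output: one row per (family, k) with mean, sample SD and max of
    balanced accuracy and MCC.
    """
    required = {"family", "k", "balanced_accuracy", "mcc"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results lacks column(s) {sorted(missing)}")
    if results.empty:
        raise ValueError("no results to aggregate")
    grouped = results.groupby(["family", "k"], sort=True)
    if (grouped.size() < 2).any():
        raise ValueError("each (family, k) group needs ≥ 2 repeats")
    out = grouped.agg(
        mean_ba=("balanced_accuracy", "mean"),
        sd_ba=("balanced_accuracy", lambda s: s.std(ddof=1)),
        mean_mcc=("mcc", "mean"),
        sd_mcc=("mcc", lambda s: s.std(ddof=1)),
        max_ba=("balanced_accuracy", "max"),
        max_mcc=("mcc", "max"),
        n_repeats=("balanced_accuracy", "size"),
    ).reset_index()
    return out
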