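"""Binary-classification metrics from confusion-matrix counts.

The positive class is the tumor class (glioma). Besides computing metrics
from a counted confusion matrix, :func:`confusion_from_rates` reconstructs
integer counts from a published (n_pos, n_neg, sensitivity, specificity)
tuple, so printed result rows can be re-derived and checked.

Zero denominators yield ``nan`` (an explicit "undefined" marker), never a
silent zero; the text formatting renders these as ``undef``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_from_rates",
           "compute_metrics", "round_half_up"]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round to ``decimals`` places with ties going away from zero."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for a binary problem; positive class = tumor (glioma)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_array(self):
        return [[self.tp, self.fn], [self.fp, self.tn]]


def confusion_from_rates(n_pos: int, n_neg: int, sensitivity: float,
                         specificity: float) -> ConfusionMatrix:
    """Reconstruct integer counts from class sizes and the two rates.

    ``TP = round(sensitivity * n_pos)`` (half-up) and ``TN = round(
    specificity * n_neg)``; the complements fill FN and FP.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class sizes must be non-negative")
    for name, r in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    tp = int(math.floor(sensitivity * n_pos + 0.5))
    tn = int(math.floor(specificity * n_neg + 0.5))
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics; ``nan`` marks a metric whose denominator is zero."""

    sensitivity: float
    specificity: float
    precision_pos: float
    precision_neg: float
    f1_pos: float
    f1_neg: float
    mcc: float
    accuracy: float

    def rounded(self, decimals: int = 3) -> "MetricsReport":
        return MetricsReport(**{
            k: round_half_up(v, decimals) for k, v in asdict(self).items()
        })

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, decimals: int = 3) -> str:
        d = {k: (None if math.isnan(v) else round_half_up(v, decimals))
             for k, v in asdict(self).items()}
        return json.dumps(d, indent=2)

    def format_table(self, decimals: int = 3) -> str:
        rows = []
        for k, v in asdict(self).items():
            val = "undef" if math.isnan(v) else f"{round_half_up(v, decimals):.{decimals}f}"
            rows.append(f"{k:<15} {val:>8}")
        return "\n".join(rows)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, per-class precision/F1, MCC and accuracy.

    MCC uses the count form
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; any zero
    factor makes it undefined (nan).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty (all counts zero)")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec_p = _ratio(tp, tp + fp)
    prec_n = _ratio(tn, tn + fn)
    f1_p = _ratio(2.0 * prec_p * sens, prec_p + sens) \
        if not (math.isnan(prec_p) or math.isnan(sens)) else math.nan
    f1_n = _ratio(2.0 * prec_n * spec, prec_n + spec) \
        if not (math.isnan(prec_n) or math.isnan(spec)) else math.nan
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else math.nan
    acc = (tp + tn) / cm.total
    return MetricsReport(
        sensitivity=sens, specificity=spec,
        precision_pos=prec_p, precision_neg=prec_n,
        f1_pos=f1_p, f1_neg=f1_n, mcc=mcc, accuracy=acc,
    )
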