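"""Binary classification metrics from confusion counts.

F1, Matthews correlation coefficient (MCC) and Cohen's kappa (CK) are
computed directly from TP/FP/TN/FN with HARD as the positive class by
default. Degenerate denominators evaluate to 0 with a warning so that
repeated evaluation protocols never abort on a trivial fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .seqio import EASY, HARD, POSITIVE_LABEL

_VALID = {EASY, HARD}


class DegenerateMetricWarning(UserWarning):
    """A metric's denominator vanished; the value is reported as 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    F1: float
    MCC: float
    CK: float
    Po: float
    Pe: float

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "MetricsReport":
        return cls(
            F1=f1(counts),
            MCC=mcc(counts),
            CK=cohens_kappa(counts),
            Po=observed_agreement(counts),
            Pe=chance_agreement(counts),
        )


def confusion(
    truth: Sequence[str], pred: Sequence[str], positive: str = POSITIVE_LABEL
) -> ConfusionCounts:
    """Count TP/FP/TN/FN of `pred` against `truth` for the given positive class."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} predictions")
    bad = sorted((set(truth) | set(pred)) - _VALID)
    if bad:
        raise ValueError(f"labels outside {{EASY, HARD}}: {bad}")
    if positive not in _VALID:
        raise ValueError(f"positive class must be EASY or HARD, got {positive!r}")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, pred):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 with a warning when the positive class
    is entirely absent from truth and prediction."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        warnings.warn("F1 undefined (no positives anywhere); returning 0",
                      DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return 2 * counts.TP / denom


def mcc(counts: ConfusionCounts) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 with a
    warning when any marginal is empty."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC undefined (an empty marginal); returning 0",
                      DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def observed_agreement(counts: ConfusionCounts) -> float:
    """Po = (TP + TN) / N."""
    return (counts.TP + counts.TN) / counts.total


def chance_agreement(counts: ConfusionCounts) -> float:
    """Pe = ((TP+FN)(TP+FP) + (TN+FP)(TN+FN)) / N^2."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    n = counts.total
    return ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)


def cohens_kappa(counts: ConfusionCounts) -> float:
    """CK = (Po - Pe) / (1 - Pe); 0 with a warning when Pe = 1."""
    po = observed_agreement(counts)
    pe = chance_agreement(counts)
    if pe == 1.0:
        warnings.warn("Cohen's kappa undefined (Pe = 1); returning 0",
                      DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return (po - pe) / (1.0 - pe)


def score_labels(
    truth: Sequence[str], pred: Sequence[str], positive: str = POSITIVE_LABEL
) -> MetricsReport:
    """Convenience: confusion + all metrics in one call."""
    return MetricsReport.from_counts(confusion(truth, pred, positive))
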