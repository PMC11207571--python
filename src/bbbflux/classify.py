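"""Quadrant classification of CNS penetration and its performance metrics.

Compounds are cross-classified by an in vitro efflux-ratio cutoff (2 for a
single transporter cell line, 3 for the total ER of MDR1 + BCRP) and an in
vivo K_p,uu,brain threshold of 0.3 (restricted penetration at or below the
threshold counts as positive):

    Q2 (TP): substrate and restricted   — efflux explains the restriction
    Q3 (FN): non-substrate, restricted  — restriction not due to efflux
    Q1 (FP): substrate, unrestricted    — efflux overcome by other routes
    Q4 (TN): non-substrate, unrestricted

Performance metrics are reported as integer percentages, rounded half away
from zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "Quadrant",
    "ER_CUTOFF_SINGLE",
    "ER_CUTOFF_TOTAL",
    "KPUU_CUTOFF",
    "classify_compound",
    "PerformanceMetrics",
    "summarize_performance",
    "metrics_from_counts",
    "round_half_away",
]

ER_CUTOFF_SINGLE = 2.0
ER_CUTOFF_TOTAL = 3.0
KPUU_CUTOFF = 0.3


class Quadrant(str, enum.Enum):
    Q1_FP = "Q1_FP"
    Q2_TP = "Q2_TP"
    Q3_FN = "Q3_FN"
    Q4_TN = "Q4_TN"


def classify_compound(
    er_value: float,
    kpuu_invivo: float,
    er_cutoff: float = ER_CUTOFF_SINGLE,
    kpuu_cutoff: float = KPUU_CUTOFF,
) -> Quadrant:
    """Assign a compound to a quadrant.

    Substrate iff ER >= cutoff (the boundary counts as substrate, matching
    regulatory >= 2 usage); positive iff K_p,uu <= cutoff (boundary
    inclusive).
    """
    if er_value <= 0 or kpuu_invivo <= 0:
        raise InvalidInputError("er_value and kpuu_invivo must be > 0")
    substrate = er_value >= er_cutoff
    positive = kpuu_invivo <= kpuu_cutoff
    if substrate and positive:
        return Quadrant.Q2_TP
    if substrate:
        return Quadrant.Q1_FP
    if positive:
        return Quadrant.Q3_FN
    return Quadrant.Q4_TN


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (87.5 -> 88)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class PerformanceMetrics:
    """Confusion counts and derived rates (percentages, unrounded).

    Rates with a zero denominator are ``None`` (not available), never zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    fn_rate: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self) -> dict:
        """Integer-percent view, half away from zero; None stays None."""
        out = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy", "fn_rate"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_away(v)
        return out


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> PerformanceMetrics:
    """Performance metrics from a confusion matrix.

    PPV = TP/(TP+FP), NPV = TN/(TN+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), accuracy = (TP+TN)/n, FN rate = FN/(TP+FN);
    all as percentages.
    """
    n = tp + fp + tn + fn
    return PerformanceMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=_rate(tp + tn, n),
        fn_rate=_rate(fn, tp + fn),
    )


def summarize_performance(quadrants) -> PerformanceMetrics:
    """Metrics from an iterable of :class:`Quadrant` labels."""
    quadrants = list(quadrants)
    if not quadrants:
        raise InvalidInputError("need at least one classified compound")
    counts = {q: 0 for q in Quadrant}
    for q in quadrants:
        counts[Quadrant(q)] += 1
    return metrics_from_counts(
        tp=counts[Quadrant.Q2_TP],
        fp=counts[Quadrant.Q1_FP],
        tn=counts[Quadrant.Q4_TN],
        fn=counts[Quadrant.Q3_FN],
    )
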