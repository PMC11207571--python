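"""Four-parameter-logistic IC50 estimation for MDR1 inhibitors.

The inhibitor titration measures the probe-substrate efflux ratio at seven
ascending concentrations; responses are normalized to the solvent-control
(vehicle) ER.  The dose-response model is the variable-slope four-parameter
logistic, written here in its decreasing form

    response(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill),

with hill > 0 the magnitude of the (negative) slope of the inhibition curve.

Censoring rule: if inhibition (100 - response%) does not exceed 50% at the
highest tested concentration, no fit is performed and the highest applied
concentration is reported as a lower bound on the IC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .errors import FitFailureError, InvalidInputError

__all__ = [
    "normalize_response",
    "four_param_logistic",
    "FourParamLogisticIC50",
    "DoseResponseSeries",
    "IC50Result",
    "fit_ic50",
    "correct_ic50",
    "FoldComparison",
    "flag_fold_differences",
]

CENSOR_INHIBITION_PCT = 50.0
FOLD_DIFFERENCE_THRESHOLD = 3.0


def normalize_response(er_values, vehicle_er: float):
    """Express ERs as percent of the solvent control (vehicle) ER."""
    if vehicle_er <= 0:
        raise InvalidInputError("vehicle_er must be > 0")
    return 100.0 * np.asarray(er_values, dtype=float) / vehicle_er


def four_param_logistic(c, top, bottom, log10_ic50, hill):
    """Decreasing 4PL on concentration c (same units as 10**log10_ic50)."""
    logc = np.log10(np.asarray(c, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log10_ic50)))


class FourParamLogisticIC50(BaseEstimator):
    """Variable-slope 4PL fit of %-of-control response vs concentration.

    Bounds stabilise seven-point fits: top in [50, 150]% and bottom in
    [-10, 60]% of control, IC50 within [c_min/100, c_max*100], hill in
    [0.1, 10].  Replicate responses at the same concentration are averaged
    before fitting.

    Attributes (after ``fit``): ``ic50_``, ``hill_``, ``top_``, ``bottom_``,
    ``censored_``, ``max_inhibition_pct_``.  For a censored series ``ic50_``
    is the highest tested concentration (a lower bound) and the curve
    parameters are NaN.
    """

    def __init__(
        self,
        censor_threshold_pct: float = CENSOR_INHIBITION_PCT,
        top_bounds: tuple[float, float] = (50.0, 150.0),
        bottom_bounds: tuple[float, float] = (-10.0, 60.0),
        hill_bounds: tuple[float, float] = (0.1, 10.0),
        ic50_span: float = 100.0,
    ):
        self.censor_threshold_pct = censor_threshold_pct
        self.top_bounds = top_bounds
        self.bottom_bounds = bottom_bounds
        self.hill_bounds = hill_bounds
        self.ic50_span = ic50_span

    def fit(self, concentrations, response_pct):
        c = np.asarray(concentrations, dtype=float)
        r = np.asarray(response_pct, dtype=float)
        if len(c) != len(r):
            raise InvalidInputError("concentrations and responses must align")
        if np.any(c <= 0):
            raise InvalidInputError("concentrations must be > 0")
        # average replicates per concentration, keep ascending order
        order = np.argsort(c)
        c, r = c[order], r[order]
        cu, inverse = np.unique(c, return_inverse=True)
        ru = np.array([r[inverse == i].mean() for i in range(len(cu))])
        if len(cu) < 5:
            raise InvalidInputError("need >= 5 distinct concentrations")

        self.concentrations_ = cu
        self.response_ = ru
        self.max_inhibition_pct_ = float(100.0 - ru[-1])
        if self.max_inhibition_pct_ < self.censor_threshold_pct:
            self.censored_ = True
            self.ic50_ = float(cu[-1])
            self.top_ = self.bottom_ = self.hill_ = float("nan")
            self.pcov_ = None
            return self

        lo = [self.top_bounds[0], self.bottom_bounds[0],
              np.log10(cu[0] / self.ic50_span), self.hill_bounds[0]]
        hi = [self.top_bounds[1], self.bottom_bounds[1],
              np.log10(cu[-1] * self.ic50_span), self.hill_bounds[1]]
        # midpoint crossing as IC50 start
        mid = (ru.max() + ru.min()) / 2.0
        i0 = int(np.argmin(np.abs(ru - mid)))
        p0 = [
            float(np.clip(ru.max(), *self.top_bounds)),
            float(np.clip(ru.min(), *self.bottom_bounds)),
            float(np.log10(cu[i0])),
            1.0,
        ]
        try:
            popt, pcov = curve_fit(
                four_param_logistic, cu, ru, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            raise FitFailureError(f"4PL fit did not converge: {exc}") from exc
        self.top_, self.bottom_ = float(popt[0]), float(popt[1])
        self.ic50_ = float(10.0 ** popt[2])
        self.hill_ = float(popt[3])
        self.pcov_ = pcov
        self.censored_ = False
        return self

    def predict(self, concentrations):
        if self.censored_:
            raise FitFailureError("no curve available for a censored series")
        return four_param_logistic(
            concentrations, self.top_, self.bottom_, np.log10(self.ic50_), self.hill_
        )


@dataclass(frozen=True)
class DoseResponseSeries:
    """Seven-point inhibitor titration against one probe substrate."""

    inhibitor_id: str
    substrate: str
    cell_line: str
    concentrations: tuple
    er_values: tuple
    vehicle_er: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != len(self.er_values):
            raise InvalidInputError("concentrations and er_values must align")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise InvalidInputError("concentrations must be positive and strictly ascending")
        if self.vehicle_er <= 0:
            raise InvalidInputError("vehicle_er must be > 0")

    @property
    def response_pct(self):
        return normalize_response(self.er_values, self.vehicle_er)


@dataclass(frozen=True)
class IC50Result:
    inhibitor_id: str
    substrate: str
    cell_line: str
    ic50: float
    censored: bool
    hill_slope: float = float("nan")
    top: float = float("nan")
    bottom: float = float("nan")
    corrected_ic50: float | None = None


def fit_ic50(series: DoseResponseSeries, **kwargs) -> IC50Result:
    """Fit (or censor) one dose-response series; wrapper over the estimator."""
    est = FourParamLogisticIC50(**kwargs).fit(series.concentrations, series.response_pct)
    return IC50Result(
        inhibitor_id=series.inhibitor_id,
        substrate=series.substrate,
        cell_line=series.cell_line,
        ic50=est.ic50_,
        censored=est.censored_,
        hill_slope=est.hill_,
        top=est.top_,
        bottom=est.bottom_,
    )


def correct_ic50(result: IC50Result, cell_abundance: float) -> IC50Result:
    """Normalize an IC50 by transporter abundance (uM per pmol/mg).

    Division removes the abundance effect for inhibitors whose apparent
    potency scales with transporter amount; censoring propagates (the bound
    is scaled the same way).
    """
    if cell_abundance <= 0:
        raise InvalidInputError("cell_abundance must be > 0")
    return IC50Result(
        inhibitor_id=result.inhibitor_id,
        substrate=result.substrate,
        cell_line=result.cell_line,
        ic50=result.ic50,
        censored=result.censored,
        hill_slope=result.hill_slope,
        top=result.top,
        bottom=result.bottom,
        corrected_ic50=result.ic50 / cell_abundance,
    )


@dataclass(frozen=True)
class FoldComparison:
    fold: float
    flagged: bool
    indeterminate: bool


def flag_fold_differences(
    ic50_a: float,
    ic50_b: float,
    censored_a: bool = False,
    censored_b: bool = False,
    threshold: float = FOLD_DIFFERENCE_THRESHOLD,
) -> FoldComparison:
    """Flag a >= 3-fold difference between two IC50s as a real difference.

    Censored values are lower bounds (true IC50 at or above the reported
    concentration).  The comparison is decided from the bounds where they
    resolve it — e.g. a censored bound already >= threshold x the other value
    keeps the flag for any true value — and marked indeterminate otherwise.
    """
    if ic50_a <= 0 or ic50_b <= 0:
        raise InvalidInputError("IC50 values must be > 0")
    fold = max(ic50_a, ic50_b) / min(ic50_a, ic50_b)
    flagged = fold >= threshold
    if not censored_a and not censored_b:
        return FoldComparison(fold=fold, flagged=flagged, indeterminate=False)
    if censored_a and censored_b:
        # both true values can grow independently; any fold is reachable
        return FoldComparison(fold=fold, flagged=flagged, indeterminate=True)
    bound, other = (ic50_a, ic50_b) if censored_a else (ic50_b, ic50_a)
    if bound / other >= threshold:
        # true censored value >= bound >= threshold*other: flag is safe
        return FoldComparison(fold=fold, flagged=True, indeterminate=False)
    return FoldComparison(fold=fold, flagged=flagged, indeterminate=True)
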