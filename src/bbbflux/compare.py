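"""Cross-ortholog and cross-substrate comparison statistics.

Paired efflux-ratio or IC50 panels from two MDR1 orthologs (or two probe
substrates) are compared by ordinary linear regression (R^2, slope,
intercept, Pearson p) and by the residual standard error against the line of
identity,

    RSE = sqrt( sum_i (x_i - y_i)^2 / n ),

which is zero when the two entities agree exactly.  IC50 comparisons run on
log10-transformed values (the assays span three orders of magnitude); the ER
scale is configurable.  Dispersion of a single panel is summarized by the
interquartile range with linear-interpolation (type-7) quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateRegressionError, InsufficientDataError, InvalidInputError

__all__ = [
    "rse_identity",
    "ComparisonReport",
    "pairwise_correlation",
    "dynamic_range_iqr",
    "abundance_correct_er",
]


def rse_identity(x, y) -> float:
    """Root-mean-square deviation from the line of identity (symmetric in x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    if x.size == 0:
        raise InvalidInputError("empty series")
    return float(np.sqrt(np.mean((x - y) ** 2)))


@dataclass(frozen=True)
class ComparisonReport:
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    rse: float
    n: int
    scale: str
    fold3_outliers: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "rse": self.rse,
            "n": self.n,
            "scale": self.scale,
            "fold3_outliers": list(self.fold3_outliers),
        }


def pairwise_correlation(
    x,
    y,
    labels=None,
    scale: str = "log10",
    fold_threshold: float = 3.0,
) -> ComparisonReport:
    """OLS of y on x with RSE against identity and >= 3-fold outliers.

    ``scale='log10'`` transforms both axes before the regression and the RSE
    (values must be positive); fold outliers are always judged on the ratio
    scale, boundary inclusive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 paired values")
    if scale not in ("linear", "log10"):
        raise InvalidInputError("scale must be 'linear' or 'log10'")
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise InvalidInputError("log10 scale requires positive values")
        xs, ys = np.log10(x), np.log10(y)
    else:
        xs, ys = x, y
    if np.ptp(xs) == 0:
        raise DegenerateRegressionError("zero variance in x")
    ls = stats.linregress(xs, ys)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x > 0, np.maximum(x, y) / np.minimum(x, y), np.inf)
    out_idx = np.nonzero(ratio >= fold_threshold)[0]
    if labels is None:
        outliers = out_idx.tolist()
    else:
        labels = list(labels)
        outliers = [labels[i] for i in out_idx]

    return ComparisonReport(
        r_squared=float(ls.rvalue**2),
        slope=float(ls.slope),
        intercept=float(ls.intercept),
        p_value=float(ls.pvalue),
        rse=rse_identity(xs, ys),
        n=len(x),
        scale=scale,
        fold3_outliers=outliers,
    )


def dynamic_range_iqr(values) -> float:
    """Interquartile range Q3 - Q1 with type-7 (linear interpolation) quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError("need >= 4 values for an IQR")
    q1, q3 = np.percentile(v, [25.0, 75.0])  # numpy default is type-7
    return float(q3 - q1)


def abundance_correct_er(er, cell_abundance: float, mode: str = "active"):
    """Correct an efflux ratio for transporter abundance.

    ``mode='active'`` (default) scales only the transporter-attributable
    component: (ER - 1) / abundance + 1, so a passive-only compound (ER = 1)
    is a fixed point.  ``mode='naive'`` divides the whole ER by abundance,
    offered for sensitivity analysis.
    """
    if cell_abundance <= 0:
        raise InvalidInputError("cell_abundance must be > 0")
    er = np.asarray(er, dtype=float)
    if mode == "active":
        return (er - 1.0) / cell_abundance + 1.0
    if mode == "naive":
        return er / cell_abundance
    raise InvalidInputError("mode must be 'active' or 'naive'")
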