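"""In vitro prediction of the unbound brain-to-plasma ratio K_p,uu,brain.

Four model variants map NET efflux ratios into (0, 1]:

1. single-transporter, REF-weighted:   K = 1 / (NET_MDR1 * REF + 1)
2. total efflux burden:                K = 1 / Total ER
3. REF-weighted two-transporter:       K = 1 / (REF_M*NET_M + REF_B*NET_B + 1)
4. empirically scaled:                 K = 1 / (alpha*NET_M + beta*NET_B + 1)

The alpha/beta scaling factors of variant 4 are estimated by multistart
bounded nonlinear least squares against in vivo K_p,uu,brain observations,
with a two-stage outlier handling: compounds whose standardized residual is
2 or larger AND whose in vivo K_p,uu exceeds 1.2 (outside the model's
attainable range of (0, 1]) are excluded, and the model is refitted once.
Low-passive-permeability compounds are dropped up front, since these models
carry no permeability term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "predict_kpuu_mdr1_ref",
    "predict_kpuu_total",
    "predict_kpuu_ref",
    "predict_kpuu_scaled",
    "KpuuScalingRegressor",
    "KpuuObservation",
    "KpuuFit",
    "fit_scaling_factors",
    "PredictionSummary",
    "evaluate_prediction",
]

KPUU_MODEL_CAP = 1.2  # in vivo values above this are unreachable by the model


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError(f"{name} must be >= 0")
    return arr


def predict_kpuu_mdr1_ref(net_er_mdr1, ref):
    """K_p,uu from a single transporter's NET ER weighted by its REF."""
    m = _check_nonneg("net_er_mdr1", net_er_mdr1)
    r = np.asarray(ref, dtype=float)
    if np.any(r <= 0):
        raise InvalidInputError("ref must be > 0")
    return 1.0 / (m * r + 1.0)


def predict_kpuu_total(total_er):
    """K_p,uu as the reciprocal of the total efflux burden."""
    t = np.asarray(total_er, dtype=float)
    if np.any(t < 1):
        raise InvalidInputError("total_er must be >= 1")
    return 1.0 / t


def predict_kpuu_ref(net_er_mdr1, net_er_bcrp, ref_mdr1, ref_bcrp):
    """K_p,uu from REF-weighted MDR1 and BCRP NET ERs."""
    m = _check_nonneg("net_er_mdr1", net_er_mdr1)
    b = _check_nonneg("net_er_bcrp", net_er_bcrp)
    if ref_mdr1 <= 0 or ref_bcrp <= 0:
        raise InvalidInputError("REFs must be > 0")
    return 1.0 / (ref_mdr1 * m + ref_bcrp * b + 1.0)


def predict_kpuu_scaled(net_er_mdr1, net_er_bcrp, alpha, beta):
    """K_p,uu with empirical scaling factors replacing the REFs."""
    m = _check_nonneg("net_er_mdr1", net_er_mdr1)
    b = _check_nonneg("net_er_bcrp", net_er_bcrp)
    if alpha < 0 or beta < 0:
        raise InvalidInputError("alpha and beta must be >= 0")
    return 1.0 / (alpha * m + beta * b + 1.0)


class KpuuScalingRegressor(RegressorMixin, BaseEstimator):
    """Estimate the alpha/beta scaling factors by nonlinear least squares.

    Parameters
    ----------
    n_starts : int
        Number of uniform-random multistart initialisations drawn from
        ``start_range`` for each fit stage.  The best converged start by AIC
        wins; ties break on lower residual sum of squares, then lower alpha.
    start_range : tuple of float
        Range of the uniform start distribution for both parameters.
    log_scale : bool
        Fit on log10-transformed K_p,uu instead of the natural scale.
        Default off: the exclusion rule's 1.2 cap argument lives on the
        natural scale.
    resid_z_threshold : float
        Standardized-residual magnitude at or above which a compound is
        flagged as an outlier candidate.
    kpuu_cap : float
        Flagged compounds with observed K_p,uu above this value are excluded
        before the single refit.
    random_state : int
        Seed for the multistart draws.

    Attributes
    ----------
    alpha_, beta_ : float
        Point estimates (>= 0).
    se_alpha_, se_beta_ : float
        Wald standard errors from the Gauss-Newton covariance.
    ci95_alpha_, ci95_beta_ : tuple of float
        Wald 95% intervals with t(n_used - 2) quantiles.
    aic_ : float
        Gaussian AIC of the accepted fit (matches R's ``AIC`` for ``nls``).
    n_used_ : int
        Observations entering the accepted fit.
    excluded_ : list of dict
        Exclusion log with reason codes ``low_permeability``,
        ``kpuu_above_cap``.
    residuals_, standardized_residuals_ : ndarray
        Residual vectors of the accepted fit (aligned with the rows used).
    used_index_ : ndarray
        Indices (into the fit X) of the rows in the accepted fit.
    """

    def __init__(
        self,
        n_starts: int = 250,
        start_range: tuple[float, float] = (0.0, 5.0),
        log_scale: bool = False,
        resid_z_threshold: float = 2.0,
        kpuu_cap: float = KPUU_MODEL_CAP,
        random_state: int = 0,
    ):
        self.n_starts = n_starts
        self.start_range = start_range
        self.log_scale = log_scale
        self.resid_z_threshold = resid_z_threshold
        self.kpuu_cap = kpuu_cap
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _residual_fn(self, X, y):
        if self.log_scale:
            logy = np.log10(y)

            def fun(p):
                return logy - np.log10(1.0 / (X @ p + 1.0))

            def jac(p):
                d = X @ p + 1.0
                return X / (np.log(10.0) * d)[:, None]

        else:

            def fun(p):
                return y - 1.0 / (X @ p + 1.0)

            def jac(p):
                d = X @ p + 1.0
                return X / (d ** 2)[:, None]

        return fun, jac

    @staticmethod
    def _aic(rss: float, n: int, k: int = 2) -> float:
        # Gaussian log-likelihood AIC with sigma profiled out; k params + sigma.
        return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1)

    def _multistart(self, X, y, rng):
        fun, jac = self._residual_fn(X, y)
        n = len(y)
        best = None
        starts = rng.uniform(*self.start_range, size=(self.n_starts, 2))
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    fun, x0, jac=jac, bounds=(0.0, np.inf), method="trf"
                )
            except Exception:  # pragma: no cover - solver-internal failure
                continue
            if not res.success:
                continue
            rss = float(2.0 * res.cost)
            aic = self._aic(rss, n)
            key = (aic, rss, res.x[0])
            if best is None or key < best[0]:
                best = (key, res)
        if best is None:
            raise FitFailureError("no multistart converged")
        return best[1]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, low_permeability=None):
        """Fit alpha/beta on NET ER pairs ``X`` (n, 2) against in vivo ``y``.

        ``low_permeability`` is an optional boolean mask of compounds whose
        brain restriction is permeability-limited rather than efflux-limited;
        these are dropped before fitting.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidInputError("X must have shape (n, 2): NET ER MDR1, NET ER BCRP")
        if len(X) != len(y):
            raise InvalidInputError("X and y length mismatch")
        if np.any(X < 0):
            raise InvalidInputError("NET ERs must be >= 0")
        if np.any(y <= 0):
            raise InvalidInputError("in vivo K_p,uu must be > 0")

        rng = np.random.default_rng(self.random_state)
        idx = np.arange(len(y))
        excluded: list[dict] = []

        if low_permeability is not None:
            lp = np.asarray(low_permeability, dtype=bool)
            for i in idx[lp]:
                excluded.append({"index": int(i), "reason": "low_permeability"})
            keep = ~lp
        else:
            keep = np.ones(len(y), dtype=bool)

        use = idx[keep]
        if len(use) < 4:
            raise InsufficientDataError("need >= 4 usable observations")

        res = self._multistart(X[use], y[use], rng)
        resid = y[use] - 1.0 / (X[use] @ res.x + 1.0)
        sd = resid.std(ddof=1)
        z = resid / sd if sd > 0 else np.zeros_like(resid)
        flagged = np.abs(z) >= self.resid_z_threshold
        drop = flagged & (y[use] > self.kpuu_cap)

        if np.any(drop):
            for i in use[drop]:
                excluded.append(
                    {
                        "index": int(i),
                        "reason": "kpuu_above_cap",
                        "kpuu_invivo": float(y[i]),
                        "standardized_residual": float(z[use == i][0]),
                    }
                )
            use = use[~drop]
            if len(use) < 4:
                raise InsufficientDataError("fewer than 4 observations after exclusions")
            res = self._multistart(X[use], y[use], rng)

        self.alpha_, self.beta_ = (float(v) for v in res.x)
        self.coef_ = res.x.copy()
        self.n_used_ = int(len(use))
        self.used_index_ = use.copy()
        self.excluded_ = excluded

        fun, jac = self._residual_fn(X[use], y[use])
        r = fun(res.x)
        J = jac(res.x)
        rss = float(r @ r)
        dof = max(self.n_used_ - 2, 1)
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        self.cov_ = cov
        self.se_alpha_, self.se_beta_ = (float(np.sqrt(max(cov[i, i], 0.0))) for i in (0, 1))
        tq = stats.t.ppf(0.975, dof)
        self.ci95_alpha_ = (self.alpha_ - tq * self.se_alpha_, self.alpha_ + tq * self.se_alpha_)
        self.ci95_beta_ = (self.beta_ - tq * self.se_beta_, self.beta_ + tq * self.se_beta_)
        self.aic_ = float(self._aic(rss, self.n_used_))
        self.residuals_ = y[use] - 1.0 / (X[use] @ res.x + 1.0)
        rsd = self.residuals_.std(ddof=1)
        self.standardized_residuals_ = (
            self.residuals_ / rsd if rsd > 0 else np.zeros_like(self.residuals_)
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return 1.0 / (X @ self.coef_ + 1.0)


@dataclass(frozen=True)
class KpuuObservation:
    compound_id: str
    net_er_mdr1: float
    net_er_bcrp: float
    kpuu_invivo: float
    low_permeability_flag: bool = False


@dataclass
class KpuuFit:
    """Result bundle of a scaling-factor estimation."""

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    ci95_alpha: tuple[float, float]
    ci95_beta: tuple[float, float]
    aic: float
    n_used: int
    excluded_ids: list = field(default_factory=list)
    residuals: dict = field(default_factory=dict)
    standardized_residuals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "se_alpha": self.se_alpha,
            "se_beta": self.se_beta,
            "ci95_alpha": list(self.ci95_alpha),
            "ci95_beta": list(self.ci95_beta),
            "aic": self.aic,
            "n_used": self.n_used,
            "excluded_ids": self.excluded_ids,
            "residuals": self.residuals,
            "standardized_residuals": self.standardized_residuals,
        }


def fit_scaling_factors(observations, **kwargs) -> KpuuFit:
    """Estimate alpha/beta from :class:`KpuuObservation` records.

    Thin wrapper over :class:`KpuuScalingRegressor`; keyword arguments are
    forwarded to the estimator.
    """
    obs = list(observations)
    X = np.array([[o.net_er_mdr1, o.net_er_bcrp] for o in obs])
    y = np.array([o.kpuu_invivo for o in obs])
    lp = np.array([o.low_permeability_flag for o in obs])
    est = KpuuScalingRegressor(**kwargs).fit(X, y, low_permeability=lp)
    ids = [o.compound_id for o in obs]
    excluded = [
        {**e, "compound_id": ids[e["index"]]} for e in est.excluded_
    ]
    used_ids = [ids[i] for i in est.used_index_]
    return KpuuFit(
        alpha=est.alpha_,
        beta=est.beta_,
        se_alpha=est.se_alpha_,
        se_beta=est.se_beta_,
        ci95_alpha=est.ci95_alpha_,
        ci95_beta=est.ci95_beta_,
        aic=est.aic_,
        n_used=est.n_used_,
        excluded_ids=excluded,
        residuals=dict(zip(used_ids, est.residuals_.tolist())),
        standardized_residuals=dict(zip(used_ids, est.standardized_residuals_.tolist())),
    )


@dataclass(frozen=True)
class PredictionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    band_halfwidths: np.ndarray
    n: int
    log_scale: bool


def evaluate_prediction(predicted, observed, log_scale: bool = True) -> PredictionSummary:
    """OLS of observed on predicted K_p,uu with a 95% prediction band.

    Performed on log10-transformed values by default, matching how
    predictions spanning orders of magnitude are judged; the band half-width
    at each point is t(0.975, n-2) * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx).
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("predicted and observed must have equal length")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 points")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise InvalidInputError("log-scale regression requires positive values")
        x, y = np.log10(x), np.log10(y)
    ls = stats.linregress(x, y)
    n = len(x)
    yhat = ls.intercept + ls.slope * x
    resid = y - yhat
    dof = n - 2
    s = np.sqrt(resid @ resid / dof) if dof > 0 else 0.0
    sxx = np.sum((x - x.mean()) ** 2)
    half = stats.t.ppf(0.975, dof) * s * np.sqrt(1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx)
    return PredictionSummary(
        slope=float(ls.slope),
        intercept=float(ls.intercept),
        r_squared=float(ls.rvalue**2),
        p_value=float(ls.pvalue),
        band_halfwidths=half,
        n=n,
        log_scale=log_scale,
    )
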