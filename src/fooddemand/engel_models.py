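"""Engel-curve models for total per-capita calorie demand.

Total demand :math:`C_T` (kcal capita^-1 d^-1) is modelled as a power law
in per-capita income :math:`I` with time-dependent coefficients, in two
alternative formulations:

* ``gA`` — log-log regression with linearly time-varying coefficients,

  .. math:: g_A(I, t) = \\exp(\\alpha_1 + \\alpha_2 t)\\, I^{\\beta_1 + \\beta_2 t}

  estimated in two stages: per-year ordinary least squares of
  :math:`\\ln C_T` on :math:`\\ln I`, followed by straight-line fits of the
  yearly intercepts :math:`\\alpha^* = \\ln\\alpha` and elasticities
  :math:`\\beta` against the calendar year.

* ``gB`` — per-year power-law fits by nonlinear least squares on the
  untransformed data, with the yearly coefficient series then fitted to a
  saturating (Michaelis-Menten type) time trajectory

  .. math:: m(t) = \\omega_1 + \\omega_2 (t - t_1) / (t - t_1 + \\omega_3)

  with base year :math:`t_1 = 1960`, giving
  :math:`g_B(I, t) = m_\\alpha(t)\\, I^{m_\\beta(t)}`.

Throughout, ``t`` is the calendar year (2000 means the year 2000); only
the saturating trajectory uses the shifted time :math:`t - t_1`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import DomainError, FitError

__all__ = [
    "GAParams",
    "GBParams",
    "SaturatingCurveParams",
    "YearlyPowerFit",
    "GAFit",
    "GBFit",
    "fit_yearly_power",
    "fit_gA",
    "eval_gA",
    "fit_michaelis_menten",
    "fit_gB",
    "eval_gB",
]

_XTOL = 1e-10
_MAXFEV = 10_000


@dataclass(frozen=True)
class GAParams:
    """Coefficients of the linear-time total-calorie model gA.

    ``alpha1``/``alpha2`` are intercept and per-year slope of
    :math:`\\alpha^* = \\ln \\alpha`; ``beta1``/``beta2`` of the income
    elasticity :math:`\\beta`. Time is the calendar year.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    def alpha_star(self, year):
        return self.alpha1 + self.alpha2 * np.asarray(year, dtype=float)

    def beta(self, year):
        return self.beta1 + self.beta2 * np.asarray(year, dtype=float)


@dataclass(frozen=True)
class SaturatingCurveParams:
    """Saturating time trajectory ``omega1 + omega2*dt/(dt + omega3)``.

    ``dt = year - t1`` with base year ``t1`` (1960 by default); ``omega3``
    is the half-saturation constant in years.
    """

    omega1: float
    omega2: float
    omega3: float
    t1: float = 1960.0

    def __call__(self, year):
        dt = np.asarray(year, dtype=float) - self.t1
        denom = dt + self.omega3
        if np.any(denom == 0):
            raise DomainError(f"saturating curve pole at year {self.t1 - self.omega3}")
        return self.omega1 + self.omega2 * dt / denom


@dataclass(frozen=True)
class GBParams:
    """Saturating-time total-calorie model gB: trajectories for alpha and beta."""

    m_alpha: SaturatingCurveParams
    m_beta: SaturatingCurveParams


@dataclass(frozen=True)
class YearlyPowerFit:
    """One year's power-law fit C_T = alpha * I^beta."""

    year: int
    alpha: float
    beta: float
    rse: float  # residual standard error on the kcal scale
    n: int


@dataclass(frozen=True)
class GAFit:
    """Result of fitting gA: coefficients plus stage diagnostics."""

    params: GAParams
    r2_alpha: float  # r^2 of the stage-2 line through yearly alpha*
    r2_beta: float
    yearly: pd.DataFrame = field(repr=False)  # columns year, alpha_star, beta


@dataclass(frozen=True)
class GBFit:
    """Result of fitting gB: trajectory parameters plus stage diagnostics."""

    params: GBParams
    rse_alpha: float  # residual standard error of the alpha trajectory fit
    rse_beta: float
    yearly: pd.DataFrame = field(repr=False)  # columns year, alpha, beta, rse, n


def _check_income(income) -> np.ndarray:
    arr = np.asarray(income, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("income must be positive")
    return arr


def eval_gA(params: GAParams, income, year):
    """Evaluate gA(I, t) in kcal capita^-1 d^-1."""
    arr = _check_income(income)
    t = np.asarray(year, dtype=float)
    return np.exp(params.alpha_star(t)) * arr ** params.beta(t)


def eval_gB(params: GBParams, income, year):
    """Evaluate gB(I, t) in kcal capita^-1 d^-1."""
    arr = _check_income(income)
    t = np.asarray(year, dtype=float)
    return params.m_alpha(t) * arr ** params.m_beta(t)


def _power(I, alpha, beta):
    return alpha * I**beta


def fit_yearly_power(income, total_kcal, year: int = 0) -> YearlyPowerFit:
    """Nonlinear least-squares fit of C_T = alpha * I^beta for one year.

    Residuals are minimized on the untransformed kcal scale. Initial values
    are the geometric mean of C_T for alpha and 0.1 for beta.
    """
    I = np.asarray(income, dtype=float)
    C = np.asarray(total_kcal, dtype=float)
    ok = np.isfinite(I) & np.isfinite(C)
    I, C = I[ok], C[ok]
    if len(I) < 3:
        raise FitError(f"year {year}: need at least 3 complete (I, C_T) pairs, got {len(I)}")
    _check_income(I)
    p0 = [float(np.exp(np.mean(np.log(C)))), 0.1]
    try:
        popt, _ = curve_fit(_power, I, C, p0=p0, maxfev=_MAXFEV, xtol=_XTOL, ftol=_XTOL)
    except RuntimeError as exc:  # pragma: no cover - scipy reports iterations
        raise FitError(f"year {year}: power-law fit did not converge: {exc}") from exc
    resid = C - _power(I, *popt)
    dof = max(len(I) - 2, 1)
    return YearlyPowerFit(
        year=int(year), alpha=float(popt[0]), beta=float(popt[1]),
        rse=float(np.sqrt(resid @ resid / dof)), n=int(len(I)),
    )


def _yearly_loglog(panel: pd.DataFrame) -> pd.DataFrame:
    """Stage 1 of gA: per-year OLS of ln C_T on ln I."""
    rows = []
    for year, grp in panel.groupby("year"):
        sub = grp.dropna(subset=["income", "total_kcal"])
        if len(sub) < 3:
            warnings.warn(f"year {int(year)} skipped: fewer than 3 complete pairs")
            continue
        res = linregress(np.log(sub["income"]), np.log(sub["total_kcal"]))
        rows.append({"year": int(year), "alpha_star": res.intercept, "beta": res.slope})
    return pd.DataFrame(rows)


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)


def fit_gA(panel: pd.DataFrame, method: str = "two-stage") -> GAFit:
    """Fit the linear-time model gA on a country-year panel.

    ``method="two-stage"`` (default) runs per-year log-log regressions and
    then fits straight lines to the yearly coefficients against calendar
    year. ``method="mixed"`` fits a single linear mixed model with a
    year-level random intercept and ln-income slope, and draws the yearly
    coefficients from the predicted year effects; on well-conditioned data
    the two estimators agree closely.
    """
    if method == "mixed":
        yearly = _yearly_mixed(panel)
    elif method == "two-stage":
        yearly = _yearly_loglog(panel)
    else:
        raise FitError(f"unknown gA method {method!r}")
    if len(yearly) < 2:
        raise FitError("gA needs at least 2 years with >=3 complete pairs each")
    t = yearly["year"].to_numpy(dtype=float)
    a1, a2, r2a = _line_fit(t, yearly["alpha_star"].to_numpy())
    b1, b2, r2b = _line_fit(t, yearly["beta"].to_numpy())
    return GAFit(GAParams(a1, a2, b1, b2), r2_alpha=r2a, r2_beta=r2b, yearly=yearly)


def _yearly_mixed(panel: pd.DataFrame) -> pd.DataFrame:
    """Year-level coefficients from a mixed model with random intercept+slope.

    The fixed part is ln C_T ~ ln I; the year groups carry a random
    intercept and a random ln-income slope, so each year's coefficient pair
    is fixed effect plus predicted (BLUP) deviation.
    """
    import statsmodels.formula.api as smf

    sub = panel.dropna(subset=["income", "total_kcal"]).copy()
    sub["ln_income"] = np.log(sub["income"])
    sub["ln_total"] = np.log(sub["total_kcal"])
    if sub["year"].nunique() < 2:
        raise FitError("gA needs at least 2 years")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are fine here
        model = smf.mixedlm("ln_total ~ ln_income", sub, groups=sub["year"],
                            re_formula="~ln_income")
        # powell is the most reliable optimizer for this variance structure
        fit = model.fit(method="powell", maxiter=2000)
        if not fit.converged:
            fit = model.fit(maxiter=2000)
    rows = []
    for year, re in fit.random_effects.items():
        rows.append({
            "year": int(year),
            "alpha_star": float(fit.params["Intercept"] + re.get("Group", re.iloc[0])),
            "beta": float(fit.params["ln_income"] + re.get("ln_income", re.iloc[-1])),
        })
    return pd.DataFrame(rows).sort_values("year", ignore_index=True)


def _mm(t, o1, o2, o3, t1=1960.0):
    dt = t - t1
    return o1 + o2 * dt / (dt + o3)


def fit_michaelis_menten(years, values, t1: float = 1960.0) -> SaturatingCurveParams:
    """Nonlinear least-squares fit of the saturating time trajectory.

    The half-saturation constant is poorly conditioned when the trajectory
    is nearly flat or saturates immediately, so the optimizer is started
    from a deterministic grid of omega3 candidates (including values that
    place the bend just before the first observation) and the best
    converged solution is kept. omega3 is constrained so the pole
    ``t1 - omega3`` stays left of the first data point.
    """
    t = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise FitError(f"need at least 4 points for a saturating-curve fit, got {len(t)}")
    if np.ptp(v) < 1e-12 * max(1.0, abs(v[0])):
        warnings.warn("near-constant series: returning a flat trajectory (omega2 = 0)")
        return SaturatingCurveParams(float(v.mean()), 0.0, 1.0, t1)
    span = float(t.max() - t.min())
    dt_min = float(t.min() - t1)
    lo = -dt_min + 1e-6  # keep the pole left of the data
    grid = [g for g in (lo + 0.05, lo + 0.2, lo + 0.45, 1.0, span / 8, span / 2, span, 2 * span)
            if g > lo]
    best, best_ssr = None, np.inf
    for o3 in grid:
        p0 = [float(v[0]), float(v[-1] - v[0]), float(o3)]
        try:
            popt, _ = curve_fit(
                _mm, t, v, p0=p0, maxfev=_MAXFEV, xtol=_XTOL, ftol=_XTOL,
                bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, np.inf]),
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((v - _mm(t, *popt)) ** 2))
        if ssr < best_ssr:
            best, best_ssr = popt, ssr
    if best is None:
        raise FitError("saturating-curve fit did not converge from any start")
    return SaturatingCurveParams(float(best[0]), float(best[1]), float(best[2]), t1)


def fit_gB(panel: pd.DataFrame, t1: float = 1960.0) -> GBFit:
    """Fit the saturating-time model gB on a country-year panel.

    Stage 1 fits a power law per year on the untransformed data; stage 2
    fits saturating trajectories to the yearly alpha and beta series.
    """
    rows = []
    for year, grp in panel.groupby("year"):
        sub = grp.dropna(subset=["income", "total_kcal"])
        if len(sub) < 3:
            warnings.warn(f"year {int(year)} skipped: fewer than 3 complete pairs")
            continue
        fit = fit_yearly_power(sub["income"], sub["total_kcal"], int(year))
        rows.append({"year": fit.year, "alpha": fit.alpha, "beta": fit.beta,
                     "rse": fit.rse, "n": fit.n})
    yearly = pd.DataFrame(rows)
    if len(yearly) < 4:
        raise FitError("gB needs at least 4 years with >=3 complete pairs each")
    t = yearly["year"].to_numpy(dtype=float)
    m_alpha = fit_michaelis_menten(t, yearly["alpha"].to_numpy(), t1)
    m_beta = fit_michaelis_menten(t, yearly["beta"].to_numpy(), t1)
    rse_a = float(np.sqrt(np.mean((yearly["alpha"] - m_alpha(t)) ** 2)))
    rse_b = float(np.sqrt(np.mean((yearly["beta"] - m_beta(t)) ** 2)))
    return GBFit(GBParams(m_alpha, m_beta), rse_alpha=rse_a, rse_beta=rse_b, yearly=yearly)
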