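"""Models for the animal-based calorie share.

The share :math:`C_{LS} = C_L / C_T` of animal-derived calories (meat,
milk, eggs, fish) in total demand is modelled in two alternative ways:

* ``hA`` — a log-linear regression with an income-time interaction,

  .. math:: h_A(I, t) = \\exp(\\kappa_1 + \\kappa_2 \\ln I + \\kappa_3 t
            + \\kappa_4 t \\ln I)

  so animal products behave as a normal necessity good (Bennet's law) with
  a time-eroded income response.

* ``hB`` — a peaked curve in which an under-proportional square-root rise
  is multiplied by an exponential decline,

  .. math:: h_B(I, t) = (\\rho_1 + \\rho_2 t)\\, \\sqrt{I}\\,
            e^{-(\\lambda_1 + \\lambda_2 t) I}

  so animal products turn into an inferior good at high incomes while the
  share can never become negative. Income enters in raw US$2005 per
  capita and year; ``t`` is the calendar year in both models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, FitError

__all__ = [
    "HAParams",
    "HBParams",
    "HAFit",
    "HBFit",
    "animal_share",
    "fit_hA",
    "eval_hA",
    "fit_hB",
    "eval_hB",
]

_XTOL = 1e-10
_MAXFEV = 10_000


@dataclass(frozen=True)
class HAParams:
    """Coefficients of the log-linear share model hA (calendar-year time)."""

    kappa1: float
    kappa2: float
    kappa3: float
    kappa4: float


@dataclass(frozen=True)
class HBParams:
    """Coefficients of the peaked share model hB.

    ``rho1 + rho2*t`` is the level coefficient (per sqrt(US$)),
    ``lambda1 + lambda2*t`` the exponential decay rate (per US$).
    """

    rho1: float
    rho2: float
    lambda1: float
    lambda2: float

    def rho(self, year):
        return self.rho1 + self.rho2 * np.asarray(year, dtype=float)

    def lam(self, year):
        return self.lambda1 + self.lambda2 * np.asarray(year, dtype=float)


@dataclass(frozen=True)
class HAFit:
    params: HAParams
    r2: float
    n_dropped_zero: int  # zero-share rows excluded from the log regression


@dataclass(frozen=True)
class HBFit:
    params: HBParams
    rse: float
    n: int


def animal_share(animal_kcal, total_kcal):
    """Share of animal-based calories C_L / C_T (dimensionless, in [0, 1])."""
    C_L = np.asarray(animal_kcal, dtype=float)
    C_T = np.asarray(total_kcal, dtype=float)
    if np.any(C_T <= 0):
        raise DomainError("total calories must be positive")
    if np.any(C_L < 0) or np.any(C_L > C_T):
        raise DomainError("animal calories must lie in [0, total]")
    out = C_L / C_T
    return float(out) if out.ndim == 0 else out


def _check_income(income) -> np.ndarray:
    arr = np.asarray(income, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("income must be positive")
    return arr


def _clip_share(share, model: str):
    clipped = np.clip(share, 0.0, 1.0)
    n_out = int(np.sum((share < 0) | (share > 1)))
    if n_out:
        warnings.warn(f"{model} evaluated outside [0, 1] at {n_out} point(s); clipped")
    return clipped if np.ndim(share) else float(clipped)


def eval_hA(params: HAParams, income, year):
    """Evaluate hA(I, t); values outside [0, 1] are clipped with a warning."""
    lnI = np.log(_check_income(income))
    t = np.asarray(year, dtype=float)
    share = np.exp(params.kappa1 + params.kappa2 * lnI + params.kappa3 * t
                   + params.kappa4 * lnI * t)
    return _clip_share(share, "hA")


def eval_hB(params: HBParams, income, year):
    """Evaluate hB(I, t).

    Requires a non-negative level coefficient rho(t) and decay rate
    lambda(t) over the years requested (a negative rho would give negative
    shares, a negative lambda unbounded growth in income). The curve has a
    single interior maximum at I* = 1 / (2 lambda(t)).
    """
    I = _check_income(income)
    t = np.asarray(year, dtype=float)
    rho, lam = params.rho(t), params.lam(t)
    if np.any(rho < 0):
        raise DomainError("hB level coefficient rho(t) is negative")
    if np.any(lam < 0):
        raise DomainError("hB decay coefficient lambda(t) is negative")
    share = rho * np.sqrt(I) * np.exp(-lam * I)
    return _clip_share(share, "hB")


def _share_panel(panel: pd.DataFrame) -> pd.DataFrame:
    sub = panel.dropna(subset=["income", "total_kcal", "animal_kcal"]).copy()
    sub["share"] = animal_share(sub["animal_kcal"].to_numpy(), sub["total_kcal"].to_numpy())
    return sub


def fit_hA(panel: pd.DataFrame) -> HAFit:
    """Ordinary least squares of ln C_LS on {ln I, t, t ln I} with intercept.

    Rows with a zero share (log undefined) are dropped; their count is
    reported in the result. Requires at least 30 usable rows spanning at
    least two years (a single year makes t and t*ln I collinear).
    """
    import statsmodels.api as sm

    sub = _share_panel(panel)
    n_zero = int((sub["share"] == 0).sum())
    sub = sub[sub["share"] > 0]
    if len(sub) < 30:
        raise FitError(f"hA needs >=30 positive-share rows, got {len(sub)}")
    if sub["year"].nunique() < 2:
        raise FitError("hA needs observations from at least 2 years (collinear design)")
    lnI = np.log(sub["income"].to_numpy(dtype=float))
    t = sub["year"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([lnI, t, lnI * t]))
    res = sm.OLS(np.log(sub["share"].to_numpy()), X).fit()
    k = res.params
    return HAFit(HAParams(*map(float, k)), r2=float(res.rsquared), n_dropped_zero=n_zero)


def _hb_model(X, rho1, rho2, lam1, lam2):
    I, t = X
    return (rho1 + rho2 * t) * np.sqrt(I) * np.exp(-(lam1 + lam2 * t) * I)


def fit_hB(panel: pd.DataFrame) -> HBFit:
    """Nonlinear least squares for hB on the untransformed shares.

    A deterministic coarse grid over the decay rate lambda (with the level
    rho solved in closed form at each grid point, both time-constant) picks
    the starting point; the four coefficients are then refined jointly.
    Zero shares are retained.
    """
    sub = _share_panel(panel)
    if len(sub) < 30:
        raise FitError(f"hB needs >=30 rows, got {len(sub)}")
    if sub["year"].nunique() < 2:
        raise FitError("hB needs observations from at least 2 years")
    if (sub["share"] <= 0).all():
        raise FitError("hB: degenerate response, all shares are zero")
    I = sub["income"].to_numpy(dtype=float)
    t = sub["year"].to_numpy(dtype=float)
    y = sub["share"].to_numpy(dtype=float)
    # grid over lambda; conditional least-squares rho for each candidate
    best0, best_ssr = None, np.inf
    for lam in np.geomspace(1e-7, 1e-3, 25):
        basis = np.sqrt(I) * np.exp(-lam * I)
        rho = float(basis @ y / (basis @ basis))
        ssr = float(np.sum((y - rho * basis) ** 2))
        if ssr < best_ssr and rho > 0:
            best0, best_ssr = (rho, lam), ssr
    if best0 is None:
        raise FitError("hB: no valid starting point found")
    p0 = [best0[0], 0.0, best0[1], 0.0]
    try:
        popt, _ = curve_fit(_hb_model, (I, t), y, p0=p0,
                            maxfev=5 * _MAXFEV, xtol=_XTOL, ftol=_XTOL)
    except RuntimeError as exc:
        raise FitError(f"hB fit did not converge: {exc}") from exc
    resid = y - _hb_model((I, t), *popt)
    dof = max(len(y) - 4, 1)
    return HBFit(HBParams(*map(float, popt)),
                 rse=float(np.sqrt(resid @ resid / dof)), n=int(len(y)))
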