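"""Validation battery for the demand regressions.

Three procedures assess the fitted models:

* observed-versus-modelled linear regressions (goodness of fit),
* Mann-Kendall trend tests on short regional series, with the trend slope
  reported as a median of pairwise differences, and
* a subsample bootstrap: refit each model many times on a random fraction
  of the data pairs, compare the coefficients to the full-data fit as
  ratios, and score out-of-sample fit on the held-out remainder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from . import params_io
from .engel_models import eval_gA, eval_gB, fit_gA, fit_gB
from .errors import FitError
from .share_models import animal_share, eval_hA, eval_hB, fit_hA, fit_hB

__all__ = [
    "FitQuality",
    "TrendResult",
    "SensitivityResult",
    "goodness_of_fit",
    "mann_kendall",
    "bootstrap_sensitivity",
]


@dataclass(frozen=True)
class FitQuality:
    """OLS of observed on modelled values: observed = a + b * modelled."""

    intercept: float
    slope: float
    r2: float
    p_value: float
    f_statistic: float
    n: int


def goodness_of_fit(observed, modelled) -> FitQuality:
    """Linear regression of an observed series on a modelled series."""
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modelled, dtype=float)
    if len(obs) != len(mod) or len(obs) < 3:
        raise FitError("goodness_of_fit needs equal-length series of >=3 points")
    if np.ptp(mod) == 0:
        raise FitError("modelled series has zero variance")
    res = linregress(mod, obs)
    n = len(obs)
    r2 = float(res.rvalue**2)
    f = r2 / (1.0 - r2) * (n - 2) if r2 < 1.0 else math.inf
    return FitQuality(float(res.intercept), float(res.slope), r2,
                      float(res.pvalue), float(f), n)


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test outcome for one series."""

    s: int
    var_s: float
    p_value: float
    slope: float  # series units per year
    significant: bool  # at p < 0.05


def _mk_score(v: np.ndarray) -> int:
    diff = np.sign(v[None, :] - v[:, None])
    return int(np.triu(diff, 1).sum())


def _mk_variance(v: np.ndarray) -> float:
    """Tie-corrected variance of the Mann-Kendall S statistic."""
    n = len(v)
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(v, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0


def _mk_p(s: int, var: float) -> float:
    if var <= 0:  # all values tied
        return 1.0
    z = (s - np.sign(s)) / math.sqrt(var)  # continuity correction
    return float(math.erfc(abs(z) / math.sqrt(2.0)))


def _trend_slope(years: np.ndarray, v: np.ndarray, rule: str) -> float:
    if rule == "consecutive":
        return float(np.median(np.diff(v) / np.diff(years)))
    if rule == "sen":
        i, j = np.triu_indices(len(v), 1)
        return float(np.median((v[j] - v[i]) / (years[j] - years[i])))
    raise FitError(f"unknown slope rule {rule!r}")


def mann_kendall(years, values, slope_rule: str = "consecutive",
                 covariate=None, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall monotone-trend test with a median-difference slope.

    ``slope_rule="consecutive"`` (default) takes the median of successive
    differences divided by the year step; ``"sen"`` the median over all
    pairwise slopes. Passing a ``covariate`` series switches to the
    partial Mann-Kendall test, which removes the covariate's influence
    from the test statistic via the rank-based covariance of the two MK
    scores before computing the p-value.
    """
    t = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise FitError("Mann-Kendall test needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise FitError("years must be strictly increasing")
    s = _mk_score(v)
    var = _mk_variance(v)
    if covariate is None:
        p = _mk_p(s, var)
        s_eff = s
    else:
        x = np.asarray(covariate, dtype=float)
        if len(x) != len(v):
            raise FitError("covariate length mismatch")
        s_x = _mk_score(x)
        n = len(v)
        k = int(np.triu(np.sign(np.subtract.outer(v, v).T)
                        * np.sign(np.subtract.outer(x, x).T), 1).sum())
        r_v, r_x = rankdata(v), rankdata(x)
        gamma = (k + 4.0 * float(r_v @ r_x) - n * (n + 1) ** 2) / 3.0
        var_x = _mk_variance(x)
        if var_x <= 0:
            p = _mk_p(s, var)
            s_eff = s
        else:
            s_eff = s - gamma / var_x * s_x
            var_c = var - gamma**2 / var_x
            p = 1.0 if var_c <= 0 else float(math.erfc(abs(s_eff / math.sqrt(var_c)) / math.sqrt(2.0)))
    slope = _trend_slope(t, v, slope_rule)
    return TrendResult(s=int(s), var_s=float(var), p_value=float(p),
                       slope=slope, significant=bool(p < alpha))


# --- bootstrap sensitivity ---------------------------------------------------

def _fit_coefs(model_id: str, panel: pd.DataFrame) -> dict[str, float]:
    fitter = {"gA": fit_gA, "gB": fit_gB, "hA": fit_hA, "hB": fit_hB}[model_id]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fitter(panel)
    return params_io.flatten_params(model_id, result.params)


def _predict(model_id: str, coefs: dict[str, float], panel: pd.DataFrame) -> np.ndarray:
    params = params_io.unflatten_params(model_id, coefs)
    ev = {"gA": eval_gA, "gB": eval_gB, "hA": eval_hA, "hB": eval_hB}[model_id]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(ev(params, panel["income"].to_numpy(),
                             panel["year"].to_numpy(dtype=float)))


def _observed(model_id: str, panel: pd.DataFrame) -> np.ndarray:
    if model_id in ("gA", "gB"):
        return panel["total_kcal"].to_numpy(dtype=float)
    return animal_share(panel["animal_kcal"].to_numpy(), panel["total_kcal"].to_numpy())


@dataclass(frozen=True)
class SensitivityResult:
    """Subsample-bootstrap stability summary for one model."""

    model: str
    n_reps: int
    fraction: float
    seed: int
    full_coefs: dict[str, float]
    full_r2: float
    ratios: pd.DataFrame = field(repr=False)  # one row per replicate
    heldout_r2: np.ndarray = field(repr=False)
    n_failed: int = 0

    @property
    def ratio_median(self) -> pd.Series:
        return self.ratios.median()

    @property
    def ratio_sd(self) -> pd.Series:
        return self.ratios.std()


def bootstrap_sensitivity(panel: pd.DataFrame, model_id: str,
                          n_reps: int = 1000, fraction: float = 0.67,
                          seed: int = 0) -> SensitivityResult:
    """Refit a model on random subsamples of the complete data pairs.

    Each replicate draws ``floor(fraction * N)`` rows without replacement
    (N = complete data pairs), refits, and records (a) the ratio of every
    coefficient to its full-data value and (b) the r-squared of the
    observed-versus-modelled regression on the held-out rows. Replicate
    seeds derive deterministically from ``seed`` and the replicate index.
    """
    if not 0 < fraction <= 1:
        raise FitError("fraction must be in (0, 1]")
    complete = panel.dropna(subset=["income", "total_kcal", "animal_kcal"]).reset_index(drop=True)
    n = len(complete)
    full_coefs = _fit_coefs(model_id, complete)
    full_r2 = goodness_of_fit(_observed(model_id, complete),
                              _predict(model_id, full_coefs, complete)).r2
    m = int(math.floor(fraction * n))
    rows, heldout, failed = [], [], 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        idx = rng.choice(n, size=m, replace=False)
        sub = complete.iloc[np.sort(idx)]
        rest = complete.drop(complete.index[idx])
        try:
            coefs = _fit_coefs(model_id, sub)
        except FitError:
            failed += 1
            continue
        rows.append({k: coefs[k] / full_coefs[k] for k in full_coefs})
        if len(rest) >= 3:
            heldout.append(goodness_of_fit(_observed(model_id, rest),
                                           _predict(model_id, coefs, rest)).r2)
    if not rows:
        raise FitError("all bootstrap replicates failed")
    return SensitivityResult(
        model=model_id, n_reps=n_reps, fraction=fraction, seed=seed,
        full_coefs=full_coefs, full_r2=full_r2,
        ratios=pd.DataFrame(rows), heldout_r2=np.asarray(heldout),
        n_failed=failed,
    )
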