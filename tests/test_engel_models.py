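import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fooddemand as fd
from fooddemand import DomainError, FitError
from fooddemand.params_io import flatten_params

from conftest import rel_err

REF_GA = fd.REFERENCE_GA
REF_GB = fd.REFERENCE_GB


# --- evaluation --------------------------------------------------------------

@pytest.mark.parametrize("year,printed", [(2000, 3587.0), (2100, 4289.0)])
def test_eval_gA_reproduces_high_income_trajectory(year, printed):
    """gA at 60,000 US$ matches the published trajectory to coefficient rounding."""
    assert rel_err(fd.eval_gA(REF_GA, 60000.0, year), printed) < 0.005


@pytest.mark.parametrize("year,printed", [(2000, 3661.0), (2100, 3805.0)])
def test_eval_gB_reproduces_high_income_trajectory(year, printed):
    assert rel_err(fd.eval_gB(REF_GB, 60000.0, year), printed) < 0.005


def test_income_elasticity_1961_rounds_to_published_value():
    assert round(float(REF_GA.beta(1961)), 3) == 0.101


def test_eval_gA_unit_income_is_exp_alpha1():
    p = fd.GAParams(alpha1=2.0, alpha2=0.0, beta1=0.3, beta2=0.0)
    assert fd.eval_gA(p, 1.0, 2050) == pytest.approx(np.exp(2.0))


def test_eval_gB_time_invariant_when_flat():
    flat = fd.GBParams(fd.SaturatingCurveParams(1000.0, 0.0, 5.0),
                       fd.SaturatingCurveParams(0.1, 0.0, 5.0))
    v = [fd.eval_gB(flat, 5000.0, y) for y in (1961, 2000, 2100)]
    assert np.ptp(v) == 0.0


@pytest.mark.parametrize("fn,params", [(fd.eval_gA, REF_GA), (fd.eval_gB, REF_GB)])
def test_eval_rejects_nonpositive_income(fn, params):
    with pytest.raises(DomainError):
        fn(params, 0.0, 2000)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(beta1=st.floats(0.02, 0.8), alpha1=st.floats(1.0, 8.0),
       year=st.integers(1961, 2100))
def test_eval_gA_monotone_in_income_for_positive_elasticity(beta1, alpha1, year):
    p = fd.GAParams(alpha1=alpha1, alpha2=0.0, beta1=beta1, beta2=0.0)
    incomes = np.geomspace(100.0, 1e5, 25)
    values = fd.eval_gA(p, incomes, year)
    assert np.all(np.diff(values) > 0)


def test_eval_gB_monotone_in_income_on_reference():
    incomes = np.geomspace(100.0, 1e5, 50)
    for year in (1961, 2000, 2100):
        assert np.all(np.diff(fd.eval_gB(REF_GB, incomes, year)) > 0)


# --- yearly power-law fits ---------------------------------------------------

def test_fit_yearly_power_recovers_noiseless():
    rng = np.random.default_rng(0)
    I = rng.uniform(300, 60000, 80)
    C = 900.0 * I**0.10
    fit = fd.fit_yearly_power(I, C, 1999)
    assert rel_err(fit.alpha, 900.0) < 1e-6
    assert rel_err(fit.beta, 0.10) < 1e-6


def test_fit_yearly_power_flat_series_gives_zero_elasticity():
    I = np.array([500.0, 2000.0, 9000.0, 40000.0])
    fit = fd.fit_yearly_power(I, np.full(4, 2500.0))
    assert abs(fit.beta) < 1e-8
    assert fit.alpha == pytest.approx(2500.0)


def test_fit_yearly_power_needs_three_pairs():
    with pytest.raises(FitError, match="3"):
        fd.fit_yearly_power([1000.0, 2000.0], [2100.0, 2300.0])


# --- gA ----------------------------------------------------------------------

def test_fit_gA_recovers_generating_coefficients(panel_A_clean):
    fit = fd.fit_gA(panel_A_clean)
    for name, true in flatten_params("gA", REF_GA).items():
        assert rel_err(getattr(fit.params, name), true) < 1e-3
    assert fit.r2_alpha > 0.999 and fit.r2_beta > 0.999


def test_fit_gA_single_year_errors():
    panel = fd.gen_panel(fd.preset("reference-A", n_countries=30, seed=1,
                                   start_year=2000, end_year=2001))
    with pytest.raises(FitError):
        fd.fit_gA(panel[panel.year == 2000])


def test_fit_gA_mixed_model_agrees_with_two_stage():
    panel = fd.gen_panel(fd.preset("reference-A", n_countries=40, seed=5,
                                   sigma_total=0.01, sigma_share=0.0))
    two = fd.fit_gA(panel, method="two-stage").params
    mix = fd.fit_gA(panel, method="mixed").params
    for name in ("alpha1", "alpha2", "beta1", "beta2"):
        assert rel_err(getattr(mix, name), getattr(two, name)) < 0.05


# --- saturating trajectories -------------------------------------------------

def test_fit_michaelis_menten_recovers_reference_alpha_curve():
    years = np.arange(1961, 2008, dtype=float)
    truth = fd.SaturatingCurveParams(933.9, 387.5, 9.775)
    fit = fd.fit_michaelis_menten(years, truth(years))
    for name in ("omega1", "omega2", "omega3"):
        assert rel_err(getattr(fit, name), getattr(truth, name)) < 1e-4


def test_fit_michaelis_menten_constant_series():
    years = np.arange(1970, 1990, dtype=float)
    with pytest.warns(UserWarning, match="near-constant"):
        fit = fd.fit_michaelis_menten(years, np.full(20, 5.5))
    assert fit.omega1 == pytest.approx(5.5)
    assert fit.omega2 == 0.0


def test_fit_michaelis_menten_needs_four_points():
    with pytest.raises(FitError, match="4"):
        fd.fit_michaelis_menten([1961, 1962, 1963], [1.0, 2.0, 3.0])


def test_saturating_curve_pole_is_domain_error():
    curve = fd.SaturatingCurveParams(1.0, 1.0, -5.0)
    with pytest.raises(DomainError):
        curve(1965)


def test_stage2_residuals_shrink_as_trajectory_approaches_saturating_form():
    """The trajectory-fit residual decreases as the perturbation away from a
    true saturating curve is scaled down (residuals computed directly)."""
    years = np.arange(1961, 2008, dtype=float)
    base = fd.SaturatingCurveParams(933.9, 387.5, 9.775)(years)
    wiggle = np.sin((years - 1961) / 3.0)
    rses = []
    for eps in (30.0, 3.0, 0.0):
        fit = fd.fit_michaelis_menten(years, base + eps * wiggle)
        resid = (base + eps * wiggle) - fd.SaturatingCurveParams(
            fit.omega1, fit.omega2, fit.omega3)(years)
        rses.append(float(np.sqrt(np.mean(resid**2))))
    assert rses[0] > rses[1] > rses[2] - 1e-12
    assert rses[2] < 1e-6


# --- gB ----------------------------------------------------------------------

def test_fit_gB_recovers_generating_coefficients(panel_B_clean):
    fit = fd.fit_gB(panel_B_clean)
    est = flatten_params("gB", fit.params)
    for name, true in flatten_params("gB", REF_GB).items():
        if name.endswith("t1"):
            continue
        assert rel_err(est[name], true) < 1e-3, name


def test_fit_gB_mean_elasticity_matches_published_summary(panel_B_clean):
    """Yearly elasticities on a reference-surface panel average to the
    published 9.88e-2."""
    fit = fd.fit_gB(panel_B_clean)
    assert abs(fit.yearly["beta"].mean() - 9.88e-2) < 1.5e-3


def test_fit_gB_single_year_errors(panel_B_clean):
    with pytest.raises(FitError):
        fd.fit_gB(panel_B_clean[panel_B_clean.year == 1961])
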