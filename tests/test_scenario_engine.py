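import numpy as np
import pandas as pd
import pytest

import fooddemand as fd
from fooddemand import ScenarioError


@pytest.fixture(scope="module")
def scenario_A():
    return fd.gen_scenario(fd.preset("reference-A", n_countries=25, seed=8), "A1")


@pytest.fixture(scope="module")
def binding_A():
    return fd.bind_storyline("A1", fd.REFERENCE_PARAMS)


@pytest.fixture(scope="module")
def percap_A(binding_A, scenario_A):
    return fd.project_percap(binding_A, scenario_A)


@pytest.fixture(scope="module")
def observed_A(percap_A):
    """Base-year observations deviating up to +-20% from the projection."""
    obs = percap_A[percap_A.year == 1990][["country", "vegetal_kcal", "animal_kcal"]].copy()
    rng = np.random.default_rng(21)
    dev = rng.uniform(0.8, 1.2, len(obs))
    obs["vegetal_kcal"] *= dev
    obs["animal_kcal"] *= dev
    return obs.reset_index(drop=True)


# --- storyline binding -------------------------------------------------------

@pytest.mark.parametrize("tag,total,share", [
    ("A1", "gA", "hA"), ("A2", "gA", "hA"), ("B1", "gB", "hB"), ("B2", "gB", "hB"),
])
def test_storylines_bind_to_their_model_pairs(tag, total, share):
    b = fd.bind_storyline(tag, fd.REFERENCE_PARAMS)
    assert (b.total_model, b.share_model) == (total, share)


def test_custom_binding_accepts_explicit_pair():
    b = fd.bind_storyline("custom", fd.REFERENCE_PARAMS,
                          total_model="gB", share_model="hA")
    assert (b.total_model, b.share_model) == ("gB", "hA")


def test_unknown_tag_without_pair_errors():
    with pytest.raises(ScenarioError, match="unknown storyline"):
        fd.bind_storyline("X9", fd.REFERENCE_PARAMS)


def test_binding_requires_fitted_parameters():
    with pytest.raises(ScenarioError, match="no fitted parameters"):
        fd.bind_storyline("A1", {"gA": fd.REFERENCE_GA})


# --- projection --------------------------------------------------------------

def test_percap_components_sum_to_total(percap_A, binding_A, scenario_A):
    assert np.allclose(percap_A.vegetal_kcal + percap_A.animal_kcal,
                       percap_A.total_kcal, rtol=1e-9)
    # identity oracle: total recomputed from the bound model at every grid point
    recomputed = binding_A.total(scenario_A.data["income"].to_numpy(),
                                 scenario_A.data["year"].to_numpy(dtype=float))
    assert np.allclose(percap_A.total_kcal, recomputed, rtol=1e-12)


def test_percap_split_arithmetic():
    assert 3000.0 * (1 - 0.2) == 2400.0 and 3000.0 * 0.2 == 600.0  # definitional
    params = dict(fd.REFERENCE_PARAMS)
    params["hB"] = fd.HBParams(0.0, 0.0, 1e-5, 0.0)  # share identically zero
    binding = fd.bind_storyline("custom", params, total_model="gA", share_model="hB")
    scen = fd.gen_scenario(fd.preset("reference-A", n_countries=5, seed=8), "A1")
    out = fd.project_percap(binding, scen)
    assert np.allclose(out.animal_kcal, 0.0)
    assert np.allclose(out.vegetal_kcal, out.total_kcal)


def test_out_of_range_share_aborts_projection(scenario_A):
    params = dict(fd.REFERENCE_PARAMS)
    params["hA"] = fd.HAParams(kappa1=0.5, kappa2=0.0, kappa3=0.0, kappa4=0.0)
    binding = fd.bind_storyline("custom", params, total_model="gA", share_model="hA")
    with pytest.raises(ScenarioError, match="refusing"):
        fd.project_percap(binding, scenario_A)


# --- convergence blend -------------------------------------------------------

def test_conv_boundary_and_midpoint():
    assert fd.conv(3000.0, 2500.0, 1990, 2100, 1990) == 2500.0
    assert fd.conv(3000.0, 2500.0, 1990, 2100, 2100) == 3000.0
    assert fd.conv(3000.0, 2500.0, 1990, 2100, 2045) == pytest.approx(2750.0)
    assert fd.conv(3000.0, 2500.0, 1990, 2100, 2150) == 3000.0


def test_conv_before_start_errors():
    with pytest.raises(ScenarioError):
        fd.conv(3000.0, 2500.0, 1990, 2100, 1980)


def test_conv_continuous_at_convergence_year():
    ts = np.array([2099.0, 2100.0, 2101.0])
    vals = fd.conv(np.full(3, 3000.0), 2500.0, 1990, 2100, ts)
    assert abs(vals[1] - vals[0]) < 5.0  # one year's blend step
    assert vals[1] == vals[2] == 3000.0


# --- calibration -------------------------------------------------------------

def test_converge_mode_reproduces_base_year(percap_A, observed_A):
    calib = fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A))
    base = calib[calib.year == 1990].set_index("country")
    obs = observed_A.set_index("country")
    for col in ("vegetal_kcal", "animal_kcal"):
        assert np.allclose(base.loc[obs.index, col], obs[col], rtol=1e-12)


def test_preserve_mode_keeps_percentage_deviation(percap_A, observed_A):
    calib = fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A, mode="preserve"))
    merged = calib.merge(percap_A, on=["country", "year"], suffixes=("_cal", "_raw"))
    obs = observed_A.set_index("country")
    base = percap_A[percap_A.year == 1990].set_index("country")
    ratio0 = (obs["vegetal_kcal"] / base["vegetal_kcal"]).loc[merged.country].to_numpy()
    assert np.allclose(merged["vegetal_kcal_cal"] / merged["vegetal_kcal_raw"], ratio0,
                       rtol=1e-12)


def test_calibrated_components_still_sum_to_total(percap_A, observed_A):
    for mode in ("converge", "preserve"):
        calib = fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A, mode=mode))
        assert np.allclose(calib.vegetal_kcal + calib.animal_kcal, calib.total_kcal,
                           rtol=1e-9)


def test_missing_base_year_observation_names_country(percap_A, observed_A):
    with pytest.raises(ScenarioError, match=observed_A.country.iloc[0]):
        fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A.iloc[1:]))


def test_preserve_mode_spreads_countries_wider_than_converge(percap_A, observed_A):
    """With countries deviating +-20% in the base year, the 2100 cross-country
    dispersion is larger when peculiarities are preserved (direct sd oracle)."""
    conv_t = fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A))
    pres_t = fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A, mode="preserve"))
    sd_conv = conv_t[conv_t.year == 2100]["total_kcal"].std()
    sd_pres = pres_t[pres_t.year == 2100]["total_kcal"].std()
    assert sd_pres > sd_conv


def test_converge_deviation_shrinks_monotonically(percap_A, observed_A):
    """The spread of calibrated-minus-projected demand decays linearly to zero
    by the convergence year under the converge blend."""
    calib = fd.calibrate(percap_A, fd.CalibrationSpec(observed=observed_A))
    dev = calib.merge(percap_A, on=["country", "year"], suffixes=("_cal", "_raw"))
    dev["gap"] = dev["vegetal_kcal_cal"] - dev["vegetal_kcal_raw"]
    spread = dev.groupby("year")["gap"].apply(lambda g: float(np.abs(g).mean()))
    assert np.all(np.diff(spread.to_numpy()) < 1e-9)
    assert spread.loc[2100] == pytest.approx(0.0, abs=1e-9)


# --- totals and aggregation --------------------------------------------------

def test_totals_constants():
    calib = pd.DataFrame({"country": ["AAA", "BBB"], "year": [2050, 2050],
                          "vegetal_kcal": [2500.0, 2500.0], "animal_kcal": [0.0, 0.0],
                          "total_kcal": [2500.0, 2500.0]})
    pop = pd.DataFrame({"country": ["AAA", "BBB"], "year": [2050, 2050],
                        "population": [1e9, 0.0]})
    out = fd.totals(calib, pop)
    assert out.set_index("country").loc["AAA", "vegetal_EJ"] == pytest.approx(
        2500.0 * 4184.0 * 365.0 * 1e9 / 1e18)
    assert out.set_index("country").loc["BBB", "vegetal_EJ"] == 0.0


def test_totals_sum_matches_pooled_weighted_mean(percap_A, scenario_A):
    """Sum of country energy equals energy of the population-weighted mean
    demand times world population (algebraic identity)."""
    E = fd.totals(percap_A, scenario_A.data)
    merged = percap_A.merge(scenario_A.data, on=["country", "year"])
    for year, grp in merged.groupby("year"):
        pooled = np.average(grp["vegetal_kcal"], weights=grp["population"])
        world = pooled * grp["population"].sum() * 4184.0 * 365.0 / 1e18
        assert world == pytest.approx(E[E.year == year]["vegetal_EJ"].sum(), rel=1e-12)


def test_regional_weighted_means():
    table = pd.DataFrame({"country": ["AAA", "BBB"], "year": [2000, 2000],
                          "total_kcal": [2000.0, 3000.0]})
    pop = pd.DataFrame({"country": ["AAA", "BBB"], "year": [2000, 2000],
                        "population": [1.0, 1.0]})
    rmap = pd.Series({"AAA": "R", "BBB": "R"})
    out = fd.aggregate_regions(table, rmap, pop)
    assert out.loc[0, "total_kcal"] == pytest.approx(2500.0)
    pop["population"] = [1.0, 3.0]
    out = fd.aggregate_regions(table, rmap, pop)
    assert out.loc[0, "total_kcal"] == pytest.approx(2750.0)


def test_world_totals_invariant_to_partition(percap_A, scenario_A):
    E = fd.totals(percap_A, scenario_A.data)
    countries = sorted(E.country.unique())
    part1 = pd.Series({c: "R1" if i % 2 else "R2" for i, c in enumerate(countries)})
    part2 = pd.Series({c: "S1" if i < len(countries) // 3 else "S2"
                       for i, c in enumerate(countries)})
    w1 = fd.aggregate_regions(E, part1).groupby("year")["vegetal_EJ"].sum()
    w2 = fd.aggregate_regions(E, part2).groupby("year")["vegetal_EJ"].sum()
    assert np.allclose(w1.to_numpy(), w2.to_numpy(), rtol=1e-12)


def test_unmapped_country_errors(percap_A, scenario_A):
    E = fd.totals(percap_A, scenario_A.data)
    with pytest.raises(ScenarioError, match="without region"):
        fd.aggregate_regions(E, pd.Series({"C000": "R"}))
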