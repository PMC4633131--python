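"""Synthetic country-year panels and scenario inputs.

The generator emulates the statistical structure of the historical
FAOSTAT / World Bank panel the demand regressions are fitted on: about
160 countries observed yearly over 1961-2007, log-normally distributed
per-capita incomes following persistent geometric growth, and calorie
variables generated from one total-calorie model and one share model plus
multiplicative log-normal noise.

Noise is country-persistent by default (one log-normal factor per
country, constant over time). This mimics national dietary peculiarities
that persist across years — the same feature the convergence calibration
is designed to absorb — and it reproduces the smooth yearly-coefficient
series seen in the historical data; fully independent noise per
country-year is available via ``noise_structure="iid"``.

``REFERENCE_*`` hold the coefficient sets estimated from the historical
1961-2007 panel, so realistic reference panels are one call away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engel_models import GAParams, GBParams, SaturatingCurveParams, eval_gA, eval_gB
from .errors import ConfigError, PanelValidationError
from .panel_io import PANEL_COLUMNS, REGIONS
from .scenario_engine import ScenarioInput
from .share_models import HAParams, HBParams, eval_hA, eval_hB

__all__ = [
    "REFERENCE_GA",
    "REFERENCE_GB",
    "REFERENCE_HA",
    "REFERENCE_HB",
    "REFERENCE_PARAMS",
    "SynthSpec",
    "preset",
    "gen_panel",
    "gen_scenario",
    "gen_region_map",
    "inject_missingness",
]

#: Reference coefficients estimated from the historical 1961-2007 panel.
REFERENCE_GA = GAParams(alpha1=2.825, alpha2=2.131e-3, beta1=0.162, beta2=-3.124e-5)
REFERENCE_GB = GBParams(
    m_alpha=SaturatingCurveParams(933.9, 387.5, 9.775),
    m_beta=SaturatingCurveParams(8.941e-2, 8.445e-3, -0.7557),
)
REFERENCE_HA = HAParams(kappa1=-36.73, kappa2=4.497, kappa3=1.604e-2, kappa4=-2.077e-3)
REFERENCE_HB = HBParams(rho1=1.372e-2, rho2=-5.295e-6, lambda1=-1.102e-4, lambda2=6.404e-8)

REFERENCE_PARAMS = {"gA": REFERENCE_GA, "gB": REFERENCE_GB,
                    "hA": REFERENCE_HA, "hB": REFERENCE_HB}

_TOTAL_EVAL = {"gA": eval_gA, "gB": eval_gB}
_SHARE_EVAL = {"hA": eval_hA, "hB": eval_hB}

#: Storyline driver profiles: (income growth multiplier, year population
#: growth reaches zero). Globalized worlds (A1, B1) grow richer and their
#: population peaks before 2100; regionalized worlds (A2, B2) keep growing.
STORYLINE_DRIVERS = {
    "A1": (1.4, 2045),
    "A2": (0.7, 2200),
    "B1": (1.2, 2050),
    "B2": (0.9, 2125),
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic world.

    Defaults match the historical panel's dimensions (162 countries,
    1961-2007) and a realistic cross-country income distribution: initial
    log income ~ Normal(ln 2000, 1.3) US$2005, per-country growth rates ~
    Normal(2 %/a, 1.5 %/a) drawn once per country so the income ordering
    persists. Noise is multiplicative log-normal with sigma 0.1 on total
    calories and on the share.
    """

    n_countries: int = 162
    start_year: int = 1961
    end_year: int = 2007
    ln_income_mean: float = float(np.log(2000.0))
    ln_income_sd: float = 1.3
    income_growth_mean: float = 0.02
    income_growth_sd: float = 0.015
    ln_pop_mean: float = float(np.log(8e6))
    ln_pop_sd: float = 1.6
    pop_growth_mean: float = 0.018
    pop_growth_sd: float = 0.008
    total_model: str = "gA"
    total_params: object = REFERENCE_GA
    share_model: str = "hA"
    share_params: object = REFERENCE_HA
    sigma_total: float = 0.1
    sigma_share: float = 0.1
    noise_structure: str = "country"  # or "iid"
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 2:
            raise ConfigError("need at least 2 countries")
        if self.end_year <= self.start_year:
            raise ConfigError("need a year range of at least 2 years")
        if self.sigma_total < 0 or self.sigma_share < 0:
            raise ConfigError("noise sigma must be non-negative")
        if self.total_model not in _TOTAL_EVAL or self.share_model not in _SHARE_EVAL:
            raise ConfigError("unknown generating model id")
        if self.noise_structure not in ("country", "iid"):
            raise ConfigError("noise_structure must be 'country' or 'iid'")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def countries(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_countries)]


def preset(name: str, **overrides) -> SynthSpec:
    """Named reference specs.

    ``"reference-A"`` generates from the linear-time pair (gA, hA),
    ``"reference-B"`` from the saturating pair (gB, hB); both use the
    reference coefficient sets. Keyword overrides replace any spec field.
    """
    if name == "reference-A":
        spec = SynthSpec()
    elif name == "reference-B":
        spec = SynthSpec(total_model="gB", total_params=REFERENCE_GB,
                         share_model="hB", share_params=REFERENCE_HB)
    else:
        raise ConfigError(f"unknown preset {name!r}; use 'reference-A' or 'reference-B'")
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class _CountryDraws:
    ln_income0: np.ndarray
    income_growth: np.ndarray
    ln_pop0: np.ndarray
    pop_growth: np.ndarray
    u_total: np.ndarray  # persistent log-noise per country
    u_share: np.ndarray


def _draws(spec: SynthSpec) -> _CountryDraws:
    """Per-country random draws, deterministic under the spec's seed."""
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_countries
    return _CountryDraws(
        ln_income0=rng.normal(spec.ln_income_mean, spec.ln_income_sd, n),
        income_growth=rng.normal(spec.income_growth_mean, spec.income_growth_sd, n),
        ln_pop0=rng.normal(spec.ln_pop_mean, spec.ln_pop_sd, n),
        pop_growth=rng.normal(spec.pop_growth_mean, spec.pop_growth_sd, n),
        u_total=rng.normal(0.0, 1.0, n),
        u_share=rng.normal(0.0, 1.0, n),
    )


def gen_panel(spec: SynthSpec) -> pd.DataFrame:
    """Generate a historical-style country-year panel.

    Incomes follow per-country geometric growth; total calories and the
    animal share lie on the generating surfaces times multiplicative
    log-normal noise. Shares that leave (0, 1) after noise are clipped
    with a warning; a share >= 1 *before* noise raises, since that means
    the generating parameters are inconsistent.
    """
    d = _draws(spec)
    years = spec.years
    t = years[None, :].astype(float)
    income = np.exp(d.ln_income0[:, None] + d.income_growth[:, None] * (t - years[0]))
    pop = np.exp(d.ln_pop0[:, None] + d.pop_growth[:, None] * (t - years[0]))

    total_surface = _TOTAL_EVAL[spec.total_model](spec.total_params, income, t)
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # surface itself must stay inside (0, 1)
        try:
            share_surface = _SHARE_EVAL[spec.share_model](spec.share_params, income, t)
        except Warning as w:
            raise PanelValidationError(f"generating share model leaves (0, 1): {w}") from None

    rng = np.random.default_rng([spec.seed, 1])
    if spec.noise_structure == "country":
        e_total = d.u_total[:, None] * spec.sigma_total * np.ones_like(t)
        e_share = d.u_share[:, None] * spec.sigma_share * np.ones_like(t)
    else:
        e_total = rng.normal(0.0, spec.sigma_total, income.shape)
        e_share = rng.normal(0.0, spec.sigma_share, income.shape)
    total = total_surface * np.exp(e_total)
    share = share_surface * np.exp(e_share)
    n_clip = int(np.sum(share >= 1.0))
    if n_clip:
        warnings.warn(f"{n_clip} share value(s) clipped to below 1 after noise")
        share = np.minimum(share, 1.0 - 1e-9)

    nc, ny = income.shape
    return pd.DataFrame({
        "country": np.repeat(spec.countries, ny),
        "year": np.tile(years, nc),
        "income": income.ravel(),
        "population": pop.ravel(),
        "total_kcal": total.ravel(),
        "animal_kcal": (share * total).ravel(),
    })[PANEL_COLUMNS]


def gen_scenario(spec: SynthSpec, storyline: str,
                 start_year: int = 1990, end_year: int = 2100,
                 step: int = 5) -> ScenarioInput:
    """Generate scenario income/population projections for a storyline.

    The grid is 1990-2100 in 5-year steps by default. Incomes continue
    each country's historical growth path scaled by the storyline's
    income-growth multiplier; population growth declines linearly to zero
    at the storyline's peak year and turns negative after it, so the
    globalized storylines peak before 2100.
    """
    if storyline not in STORYLINE_DRIVERS:
        raise ConfigError(f"unknown storyline {storyline!r}")
    g_scale, peak_year = STORYLINE_DRIVERS[storyline]
    d = _draws(spec)
    years = np.arange(start_year, end_year + 1, step)
    dt = (years - spec.start_year)[None, :].astype(float)
    income = np.exp(d.ln_income0[:, None] + g_scale * d.income_growth[:, None] * dt)

    # population: integrate growth rate r(t) = r0 * (1 - (t - start)/(peak - start))
    span = peak_year - start_year
    tau = (years - start_year).astype(float)
    integral = tau - tau**2 / (2.0 * span)  # antiderivative of (1 - u/span)
    base = d.ln_pop0[:, None] + d.pop_growth[:, None] * (start_year - spec.start_year)
    pop = np.exp(base + d.pop_growth[:, None] * integral[None, :])

    nc, ny = income.shape
    data = pd.DataFrame({
        "country": np.repeat(spec.countries, ny),
        "year": np.tile(years, nc),
        "income": income.ravel(),
        "population": pop.ravel(),
    })
    return ScenarioInput(storyline=storyline, data=data)


def gen_region_map(spec: SynthSpec, regions: tuple[str, ...] = REGIONS) -> pd.Series:
    """Assign the spec's countries round-robin to a region set."""
    labels = [regions[i % len(regions)] for i in range(spec.n_countries)]
    return pd.Series(labels, index=pd.Index(spec.countries, name="country"), name="region")


def inject_missingness(panel: pd.DataFrame, fraction: float, seed: int = 0,
                       columns: tuple[str, ...] = ("income", "total_kcal", "animal_kcal"),
                       ) -> pd.DataFrame:
    """Blank each cell of the given columns independently with probability
    ``fraction``; the input frame is left untouched for oracle comparison."""
    if not 0 <= fraction < 1:
        raise ConfigError("missing fraction must be in [0, 1)")
    out = panel.copy()
    rng = np.random.default_rng([seed, 2])
    for col in columns:
        mask = rng.random(len(out)) < fraction
        out.loc[mask, col] = np.nan
    return out
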