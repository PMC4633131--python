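"""Scenario construction: storyline binding, projection, calibration,
totals and regional aggregation.

A storyline tag selects one total-calorie model and one share model:
the materialistic storylines (A1, A2) use the linear-time pair
``(gA, hA)``; the sustainability-oriented storylines (B1, B2) use the
saturating pair ``(gB, hB)``. Per-capita vegetal and animal demand are
projected from exogenous income paths, blended toward observed base-year
values by a convergence calibration, multiplied by population projections
and aggregated to world regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engel_models import GAParams, GBParams, eval_gA, eval_gB
from .errors import ScenarioError
from .share_models import HAParams, HBParams, eval_hA, eval_hB

__all__ = [
    "KCAL_TO_JOULE",
    "DAYS_PER_YEAR",
    "ScenarioInput",
    "StorylineBinding",
    "CalibrationSpec",
    "bind_storyline",
    "project_percap",
    "conv",
    "calibrate",
    "totals",
    "aggregate_regions",
]

#: Thermochemical kilocalorie in joules; configurable in `totals`.
KCAL_TO_JOULE = 4184.0
DAYS_PER_YEAR = 365.0

#: Storyline tag -> (total-calorie model id, share model id).
STORYLINE_MODELS = {
    "A1": ("gA", "hA"),
    "A2": ("gA", "hA"),
    "B1": ("gB", "hB"),
    "B2": ("gB", "hB"),
}

_TOTAL_EVAL = {"gA": eval_gA, "gB": eval_gB}
_SHARE_EVAL = {"hA": eval_hA, "hB": eval_hB}
_TOTAL_TYPES = {"gA": GAParams, "gB": GBParams}
_SHARE_TYPES = {"hA": HAParams, "hB": HBParams}


@dataclass(frozen=True)
class ScenarioInput:
    """Exogenous drivers of one scenario.

    ``data`` is a long-format frame (country, year, income, population) on
    a strictly increasing year grid, by default 1990-2100 in 5-year steps.
    """

    storyline: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        need = {"country", "year", "income", "population"}
        missing = need - set(self.data.columns)
        if missing:
            raise ScenarioError(f"scenario input lacks columns {sorted(missing)}")
        if (self.data["income"] <= 0).any():
            raise ScenarioError("scenario income must be positive")
        if (self.data["population"] < 0).any():
            raise ScenarioError("scenario population must be non-negative")
        years = np.sort(self.data["year"].unique())
        if len(years) < 2 or np.any(np.diff(years) <= 0):
            raise ScenarioError("scenario year grid must be strictly increasing")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())


@dataclass(frozen=True)
class StorylineBinding:
    """A storyline's concrete model pair: one total model, one share model."""

    storyline: str
    total_model: str
    total_params: object
    share_model: str
    share_params: object

    def total(self, income, year):
        return _TOTAL_EVAL[self.total_model](self.total_params, income, year)

    def share(self, income, year):
        return _SHARE_EVAL[self.share_model](self.share_params, income, year)


@dataclass(frozen=True)
class CalibrationSpec:
    """How projections are anchored to observed base-year demand.

    ``mode="converge"`` blends linearly from the observed base-year value
    to the regression value at the convergence year (national peculiarities
    vanish by ``convergence_year``); ``mode="preserve"`` keeps each
    country's base-year percentage deviation from the regression for all
    time. ``observed`` holds base-year per-capita values with columns
    country, vegetal_kcal, animal_kcal.
    """

    observed: pd.DataFrame = field(repr=False)
    base_year: int = 1990
    convergence_year: int = 2100
    mode: str = "converge"

    def __post_init__(self):
        if self.base_year >= self.convergence_year:
            raise ScenarioError("base year must precede convergence year")
        if self.mode not in ("converge", "preserve"):
            raise ScenarioError(f"unknown calibration mode {self.mode!r}")
        need = {"country", "vegetal_kcal", "animal_kcal"}
        if need - set(self.observed.columns):
            raise ScenarioError(f"observed table needs columns {sorted(need)}")
        if (self.observed[["vegetal_kcal", "animal_kcal"]] < 0).any().any():
            raise ScenarioError("observed base-year demand must be non-negative")


def bind_storyline(tag: str, params: dict,
                   total_model: str | None = None,
                   share_model: str | None = None) -> StorylineBinding:
    """Resolve a storyline tag to its model pair using a fitted-parameter store.

    ``params`` maps model ids ("gA", "gB", "hA", "hB") to fitted parameter
    objects. Unknown tags are accepted only with an explicit
    ``total_model``/``share_model`` pair.
    """
    if total_model is None or share_model is None:
        if tag not in STORYLINE_MODELS:
            raise ScenarioError(
                f"unknown storyline {tag!r}: give explicit total_model/share_model"
            )
        total_model, share_model = STORYLINE_MODELS[tag]
    for mid, types in ((total_model, _TOTAL_TYPES), (share_model, _SHARE_TYPES)):
        if mid not in types:
            raise ScenarioError(f"unknown model id {mid!r}")
        if mid not in params:
            raise ScenarioError(f"no fitted parameters for model {mid!r}")
        if not isinstance(params[mid], types[mid]):
            raise ScenarioError(f"parameters for {mid!r} have wrong type")
    return StorylineBinding(tag, total_model, params[total_model],
                            share_model, params[share_model])


def project_percap(binding: StorylineBinding, scenario: ScenarioInput) -> pd.DataFrame:
    """Raw per-capita projection: total, vegetal and animal kcal per country-year.

    vegetal = g(I,t) * (1 - h(I,t)) and animal = g(I,t) * h(I,t), so the
    two components sum to the total exactly. A share outside [0, 1] before
    clipping aborts the scenario: silently clipping would hide a model
    evaluated far outside its fitted range.
    """
    d = scenario.data
    I = d["income"].to_numpy(dtype=float)
    t = d["year"].to_numpy(dtype=float)
    total = binding.total(I, t)
    rho_ok = True
    import warnings as _warnings
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        share = binding.share(I, t)
        clipped = any("clipped" in str(w.message) for w in caught)
    if clipped:
        raise ScenarioError(
            f"share model {binding.share_model} left [0, 1] for storyline "
            f"{binding.storyline}; refusing to project"
        )
    out = d[["country", "year"]].copy()
    out["total_kcal"] = total
    out["vegetal_kcal"] = total * (1.0 - share)
    out["animal_kcal"] = total * share
    return out


def conv(x_t, c0, y_s: float, y_e: float, t):
    """Convergence blend between an observed anchor and a projection path.

    For t in [y_s, y_e] returns ((t-y_s)*X_t + (y_e-t)*C0) / (y_e-y_s); for
    t > y_e the projection X_t itself. t < y_s is outside the blend's
    domain.
    """
    x = np.asarray(x_t, dtype=float)
    tt = np.asarray(t, dtype=float)
    if np.any(tt < y_s):
        raise ScenarioError(f"conv: t < start year {y_s}")
    w = np.clip((tt - y_s) / (y_e - y_s), 0.0, 1.0)
    out = w * x + (1.0 - w) * np.asarray(c0, dtype=float)
    return float(out) if out.ndim == 0 else out


def calibrate(projection: pd.DataFrame, spec: CalibrationSpec) -> pd.DataFrame:
    """Anchor per-capita projections to observed base-year demand.

    converge mode applies the `conv` blend to the vegetal and animal series
    separately (their sum remains the calibrated total); preserve mode
    multiplies each series by the country's base-year ratio
    observed/projected for all years.
    """
    proj = projection.sort_values(["country", "year"], ignore_index=True)
    obs = spec.observed.set_index("country")
    missing = set(proj["country"]) - set(obs.index)
    if missing:
        raise ScenarioError(f"no base-year observation for {sorted(missing)[:5]}")
    base = proj[proj["year"] == spec.base_year].set_index("country")
    if base.empty:
        raise ScenarioError(f"projection does not include base year {spec.base_year}")
    out = proj.copy()
    for col in ("vegetal_kcal", "animal_kcal"):
        observed = obs.loc[proj["country"], col].to_numpy(dtype=float)
        if spec.mode == "converge":
            out[col] = conv(proj[col].to_numpy(), observed,
                            spec.base_year, spec.convergence_year,
                            proj["year"].to_numpy())
        else:  # preserve national peculiarities
            base_proj = base.loc[proj["country"], col].to_numpy(dtype=float)
            if np.any(base_proj <= 0):
                raise ScenarioError(f"zero base-year projection for {col}")
            ratio = obs.loc[proj["country"], col].to_numpy(dtype=float) / base_proj
            out[col] = proj[col].to_numpy() * ratio
    out["total_kcal"] = out["vegetal_kcal"] + out["animal_kcal"]
    return out


def totals(calibrated: pd.DataFrame, population: pd.DataFrame,
           kcal_to_joule: float = KCAL_TO_JOULE,
           days_per_year: float = DAYS_PER_YEAR) -> pd.DataFrame:
    """Total national demand E = C * P in 10^18 J a^-1.

    ``population`` is a (country, year, population) frame matching the
    calibrated table's coverage.
    """
    merged = calibrated.merge(population[["country", "year", "population"]],
                              on=["country", "year"], how="left", validate="1:1")
    if merged["population"].isna().any():
        row = merged[merged["population"].isna()].iloc[0]
        raise ScenarioError(
            f"no population for {row['country']} in {int(row['year'])}"
        )
    if (merged["population"] < 0).any():
        raise ScenarioError("negative population")
    if (merged[["vegetal_kcal", "animal_kcal"]] < 0).any().any():
        raise ScenarioError("negative per-capita demand")
    scale = kcal_to_joule * days_per_year / 1e18
    out = merged[["country", "year"]].copy()
    out["vegetal_EJ"] = merged["vegetal_kcal"] * merged["population"] * scale
    out["animal_EJ"] = merged["animal_kcal"] * merged["population"] * scale
    return out


def aggregate_regions(table: pd.DataFrame, region_map: pd.Series,
                      population: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate a country-level table to regions.

    Per-capita columns (``*_kcal``) become population-weighted means and
    need a (country, year, population) frame; total-energy columns
    (``*_EJ``) are summed.
    """
    unmapped = set(table["country"]) - set(region_map.index)
    if unmapped:
        raise ScenarioError(f"countries without region: {sorted(unmapped)[:5]}")
    df = table.copy()
    percap_cols = [c for c in df.columns if c.endswith("_kcal")]
    total_cols = [c for c in df.columns if c.endswith("_EJ")]
    if percap_cols:
        if population is None:
            raise ScenarioError("per-capita aggregation needs population weights")
        df = df.merge(population[["country", "year", "population"]],
                      on=["country", "year"], how="left", validate="1:1")
        if df["population"].isna().any():
            raise ScenarioError("missing population weight for aggregation")
    df["region"] = df["country"].map(region_map)
    rows = []
    for (region, year), grp in df.groupby(["region", "year"]):
        row = {"region": region, "year": year}
        for col in percap_cols:
            row[col] = float(np.average(grp[col], weights=grp["population"]))
        for col in total_cols:
            row[col] = float(grp[col].sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["region", "year"], ignore_index=True)
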