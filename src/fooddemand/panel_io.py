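"""Reading, validation and harmonization of country-year food-demand panels.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with one row per country-year observation and the columns

========  =====================================================
country   ISO3-style country code (string)
year      calendar year (integer)
income    per-capita income, US$2005 capita^-1 a^-1
population  population, capita
total_kcal  total calorie demand, kcal capita^-1 d^-1
animal_kcal animal-based calorie demand, kcal capita^-1 d^-1
========  =====================================================

Missing observations are encoded as NaN (empty cell or an NA literal in
files), never as zero: 0 kcal is a meaningful, invalid value.

The module also handles the harmonization steps that precede scenario
construction: currency-base deflation, regional gap filling and the
exclusion of countries without calorie statistics.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import PanelValidationError

__all__ = [
    "PANEL_COLUMNS",
    "REGIONS",
    "read_panel",
    "write_panel",
    "validate_panel",
    "complete_pairs",
    "read_region_map",
    "read_deflators",
    "deflate_income",
    "fill_missing_regional",
    "exclude_uncovered",
]

#: Canonical column order of a panel frame.
PANEL_COLUMNS = ["country", "year", "income", "population", "total_kcal", "animal_kcal"]

_NUMERIC_COLUMNS = PANEL_COLUMNS[2:]

#: Default ten-region world partition used for regional aggregation:
#: Sub-Saharan Africa, Centrally Planned Asia, Europe, Former Soviet Union,
#: Latin America, Middle East, North America, Pacific OECD, Pacific Asia,
#: South Asia.
REGIONS = ("AFR", "CPA", "EUR", "FSU", "LAM", "MEA", "NAM", "PAO", "PAS", "SAS")


def _coerce_numeric(raw: pd.Series, column: str) -> pd.Series:
    """Parse a column to float, naming the offending row on failure."""
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise PanelValidationError(
            f"malformed numeric value {raw[row]!r} in column {column!r}, row {row}"
        )
    return out.astype(float)


def validate_panel(df: pd.DataFrame, year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Check panel invariants; returns the frame unchanged on success.

    Raises
    ------
    PanelValidationError
        If required columns are missing, income is non-positive, population
        is negative, animal calories exceed total calories, or a year falls
        outside ``year_range``.
    """
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"panel is missing columns {missing}")
    if (df["income"].dropna() <= 0).any():
        bad = df.loc[df["income"] <= 0, "country"].iloc[0]
        raise PanelValidationError(f"non-positive income for country {bad!r}")
    if (df["population"].dropna() < 0).any():
        raise PanelValidationError("negative population")
    both = df["animal_kcal"].notna() & df["total_kcal"].notna()
    excess = both & (df["animal_kcal"] > df["total_kcal"])
    if excess.any():
        row = df.loc[excess].iloc[0]
        raise PanelValidationError(
            f"animal calories exceed total calories for {row['country']} in {int(row['year'])}"
        )
    if (df["animal_kcal"].dropna() < 0).any() or (df["total_kcal"].dropna() < 0).any():
        raise PanelValidationError("negative calorie value")
    if year_range is not None:
        lo, hi = year_range
        out = ~df["year"].between(lo, hi)
        if out.any():
            raise PanelValidationError(
                f"year {int(df.loc[out, 'year'].iloc[0])} outside declared range {year_range}"
            )
    return df


def read_panel(
    path,
    schema: Mapping[str, str] | None = None,
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Read a long-format country-year panel from a delimited text file.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row, comma separated).
    schema
        Optional mapping from canonical column names to the names used in
        the file, for sources whose export layout differs.
    year_range
        Optional inclusive (low, high) bound on the year column.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in PANEL_COLUMNS}
    raw = raw.rename(columns=rename)
    missing = [c for c in PANEL_COLUMNS if c not in raw.columns]
    if missing:
        raise PanelValidationError(f"file {path} lacks columns {missing}")
    df = pd.DataFrame({"country": raw["country"].astype(str)})
    df["year"] = _coerce_numeric(raw["year"], "year").astype(int)
    for col in _NUMERIC_COLUMNS:
        df[col] = _coerce_numeric(raw[col], col)
    extra = [c for c in raw.columns if c not in PANEL_COLUMNS]
    for col in extra:  # e.g. an income_base column for deflation
        df[col] = raw[col]
    return validate_panel(df, year_range)


def write_panel(df: pd.DataFrame, path) -> None:
    """Write a panel in the canonical dialect (stable digits, empty-cell NA)."""
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def complete_pairs(df: pd.DataFrame) -> int:
    """Number of rows with income and both calorie variables present."""
    return int((df["income"].notna() & df["total_kcal"].notna() & df["animal_kcal"].notna()).sum())


def read_region_map(path) -> pd.Series:
    """Read a 2-column CSV (country,region) into a country-indexed Series."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["country", "region"]:
        raise PanelValidationError("region map must have columns country,region")
    if df["country"].duplicated().any():
        dup = df.loc[df["country"].duplicated(), "country"].iloc[0]
        raise PanelValidationError(f"country {dup!r} mapped to more than one region")
    return df.set_index("country")["region"]


def read_deflators(path) -> pd.DataFrame:
    """Read a 3-column CSV (country,base_pair,factor).

    ``base_pair`` is a string like ``"US$1990->US$2005"``; a ``*`` in the
    country column declares a global fallback factor for that pair.
    """
    df = pd.read_csv(path, dtype={"country": str, "base_pair": str, "factor": float})
    if (df["factor"] <= 0).any():
        raise PanelValidationError("deflator factors must be positive")
    return df


def _lookup_factor(deflators: pd.DataFrame, country: str, pair: str) -> float:
    hit = deflators[(deflators["country"] == country) & (deflators["base_pair"] == pair)]
    if hit.empty:
        hit = deflators[(deflators["country"] == "*") & (deflators["base_pair"] == pair)]
    if hit.empty:
        raise PanelValidationError(f"no deflator for country {country!r}, base pair {pair!r}")
    return float(hit["factor"].iloc[0])


def deflate_income(
    df: pd.DataFrame,
    deflators: pd.DataFrame,
    target_base: str,
    current_base: str | None = None,
) -> pd.DataFrame:
    """Convert the income column to ``target_base`` currency units.

    The base of each record is taken from an ``income_base`` column if
    present, else from ``current_base``. Records already in the target base
    are left untouched, so the operation is idempotent.
    """
    out = df.copy()
    if "income_base" in out.columns:
        bases = out["income_base"].astype(str)
    elif current_base is not None:
        bases = pd.Series(current_base, index=out.index)
    else:
        raise PanelValidationError("no income_base column and no current_base given")
    factors = np.ones(len(out))
    for (country, base), idx in out.groupby([out["country"], bases]).groups.items():
        if base == target_base:
            continue
        factors[out.index.get_indexer(idx)] = _lookup_factor(
            deflators, str(country), f"{base}->{target_base}"
        )
    out["income"] = out["income"] * factors
    out["income_base"] = target_base
    return out


def fill_missing_regional(
    df: pd.DataFrame, region_map: pd.Series, weighted: bool = True
) -> pd.DataFrame:
    """Fill missing income/calorie cells with regional same-year averages.

    For every missing cell the average is taken over the reporting countries
    of the same region in the same year; by default the average is
    population-weighted (``weighted=False`` gives the unweighted mean, since
    the historical sources do not document the weighting). Originally
    present values are never altered.

    Raises
    ------
    PanelValidationError
        If a country is unmapped, or a region-year has no reporting donor
        for a needed variable.
    """
    unmapped = set(df["country"]) - set(region_map.index)
    if unmapped:
        raise PanelValidationError(f"countries without region: {sorted(unmapped)}")
    out = df.copy()
    region = out["country"].map(region_map)
    for col in ("income", "total_kcal", "animal_kcal"):
        miss = out[col].isna()
        if not miss.any():
            continue
        for (reg, year), idx in out.loc[miss].groupby([region[miss], out.loc[miss, "year"]]).groups.items():
            donors = out[(region == reg) & (out["year"] == year) & out[col].notna()]
            if donors.empty:
                raise PanelValidationError(
                    f"no donor for {col} in region {reg}, year {int(year)}"
                )
            if weighted and donors["population"].notna().all():
                w = donors["population"].to_numpy()
                value = float(np.average(donors[col].to_numpy(), weights=w))
            else:
                value = float(donors[col].mean())
            out.loc[idx, col] = value
    return out


def exclude_uncovered(
    df: pd.DataFrame, coverage: Iterable[str]
) -> tuple[pd.DataFrame, float]:
    """Restrict the panel to countries in ``coverage``.

    Returns the restricted panel and the share of total population held by
    the excluded country-year rows (0 when nothing is excluded, 1 for an
    empty coverage set).
    """
    coverage = set(coverage)
    keep = df["country"].isin(coverage)
    total_pop = df["population"].sum()
    if total_pop > 0:
        share = float(df.loc[~keep, "population"].sum() / total_pop)
    else:
        share = 0.0 if keep.all() else 1.0
    return df.loc[keep].reset_index(drop=True), share
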