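"""Per-capita nutrient-intake covariates from food-balance style tables.

The covariate panel assembled here has 33 columns: six nutritional measures
(N, P, N:P, kcal, protein, total kg) for each of five source categories
(terrestrial-animal, vegetable, terrestrial-animal/vegetable ratio,
aquatic-animal, alcoholic) plus three socioeconomic controls (GDP per capita,
median age, HDI).

Canonical units: intakes in kg/capita/yr, nutrient concentrations in g/kg,
energy density in kcal/kg. Elemental intakes (N, P) and protein are therefore
kg/capita/yr; energy is kcal/capita/yr. N:P is a mass ratio and unitless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_CATEGORIES = ("terrestrial-animal", "vegetable", "aquatic-animal", "alcoholic")
SOURCE_CODES = {
    "terrestrial-animal": "ta",
    "vegetable": "veg",
    "aquatic-animal": "aqa",
    "alcoholic": "alc",
}
#: derived ratio "source": elementwise terrestrial-animal / vegetable quotient
RATIO_CODE = "ta_veg"
SOURCE_COLUMN_ORDER = ("ta", "veg", "ta_veg", "aqa", "alc")
MEASURES = ("N", "P", "NP", "kcal", "protein", "total_kg")
CONTROL_COLUMNS = ("gdp_pc", "median_age", "hdi")

NUTRIENT_COLUMNS = ("n_gram_per_kg", "p_gram_per_kg", "protein_gram_per_kg", "kcal_per_kg")

_PROFILE_COLUMNS = ("N_kg", "P_kg", "NP_ratio", "protein_kg", "kcal", "total_kg")


def covariate_columns() -> list[str]:
    """The 33 panel column names, in canonical order."""
    cols = [f"{m}_{s}" for s in SOURCE_COLUMN_ORDER for m in MEASURES]
    return cols + list(CONTROL_COLUMNS)


def grams_to_kg(grams):
    """Convert grams to kilograms."""
    return np.asarray(grams, dtype=float) / 1000.0


def kg_to_grams(kg):
    """Convert kilograms to grams."""
    return np.asarray(kg, dtype=float) * 1000.0


def validate_intake_table(intake: pd.DataFrame) -> None:
    required = {"country", "year", "food_group", "source_category", "intake_kg_per_capita_yr"}
    missing = required - set(intake.columns)
    if missing:
        raise ValueError(f"intake table missing columns: {sorted(missing)}")
    if (intake["intake_kg_per_capita_yr"] < 0).any():
        raise ValueError("intake table contains negative intakes")
    bad_src = set(intake["source_category"]) - set(SOURCE_CATEGORIES)
    if bad_src:
        raise ValueError(f"unknown source categories: {sorted(bad_src)}")
    dup = intake.duplicated(subset=["country", "year", "food_group"])
    if dup.any():
        raise ValueError("duplicate (country, year, food_group) keys in intake table")


def mean_concentration(food_group: str, tables: list[pd.DataFrame]) -> pd.Series:
    """Average a food group's nutrient concentrations across databases.

    Each table holds one row per (food_group, database_id); when several
    databases report the same group, the per-nutrient arithmetic mean is the
    final value. Groups present in a single database pass through unchanged.
    """
    rows = []
    for table in tables:
        hit = table[table["food_group"] == food_group]
        if not hit.empty:
            rows.append(hit[list(NUTRIENT_COLUMNS)])
    if not rows:
        raise KeyError(f"food group {food_group!r} absent from all concentration tables")
    stacked = pd.concat(rows, ignore_index=True)
    out = stacked.mean(axis=0)
    out.name = food_group
    return out


def merge_concentrations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Database-averaged concentration rows, indexed by food group."""
    for t in tables:
        if (t[list(NUTRIENT_COLUMNS)] < 0).to_numpy().any():
            raise ValueError("negative nutrient concentration")
    stacked = pd.concat([t[["food_group", *NUTRIENT_COLUMNS]] for t in tables], ignore_index=True)
    return stacked.groupby("food_group")[list(NUTRIENT_COLUMNS)].mean()


def compute_intake_profile(intake: pd.DataFrame, conc: pd.DataFrame) -> pd.DataFrame:
    """Per (country, year, source category) nutrient intake profile.

    For every source category, each nutrient is the intake-weighted sum over
    food groups: nutrient_kg = sum(intake_kg * concentration_g_per_kg) / 1000;
    kcal = sum(intake_kg * kcal_per_kg); total_kg = sum(intake_kg). The N:P
    mass ratio is the ratio of the aggregated N and P (ratio of sums), NaN
    where the P intake is zero.
    """
    validate_intake_table(intake)
    missing = sorted(set(intake["food_group"]) - set(conc.index))
    if missing:
        raise KeyError(f"no concentration data for food groups: {missing}")

    merged = intake.merge(conc, left_on="food_group", right_index=True, how="left")
    w = merged["intake_kg_per_capita_yr"]
    merged["N_kg"] = w * merged["n_gram_per_kg"] / 1000.0
    merged["P_kg"] = w * merged["p_gram_per_kg"] / 1000.0
    merged["protein_kg"] = w * merged["protein_gram_per_kg"] / 1000.0
    merged["kcal"] = w * merged["kcal_per_kg"]
    merged["total_kg"] = w

    prof = merged.groupby(["country", "year", "source_category"])[
        ["N_kg", "P_kg", "protein_kg", "kcal", "total_kg"]
    ].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        np_ratio = prof["N_kg"] / prof["P_kg"]
    prof["NP_ratio"] = np_ratio.where(prof["P_kg"] > 0)
    return prof[list(_PROFILE_COLUMNS)]


def _decades(period: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    start, end = period
    return (start, start + 9), (end - 9, end)


def period_aggregate(values: pd.DataFrame, period: tuple[int, int], mode: str = "mean") -> pd.DataFrame:
    """Aggregate country-year values to one row per country.

    ``mean`` averages over the period; ``change`` is the mean over the
    period's last decade minus the mean over its first decade. Countries
    without any observation in a required decade are dropped with a warning.

    ``values`` must be indexed by (country, year).
    """
    start, end = period
    if start > end:
        raise ValueError(f"empty period {period}")
    years = values.index.get_level_values("year")
    in_period = values[(years >= start) & (years <= end)]
    if in_period.empty:
        raise ValueError(f"no observations within period {period}")

    if mode == "mean":
        return in_period.groupby(level="country").mean()
    if mode != "change":
        raise ValueError(f"unknown aggregation mode {mode!r}")

    (f0, f1), (l0, l1) = _decades(period)
    yrs = in_period.index.get_level_values("year")
    first = in_period[(yrs >= f0) & (yrs <= f1)].groupby(level="country").mean()
    last = in_period[(yrs >= l0) & (yrs <= l1)].groupby(level="country").mean()
    shared = first.index.intersection(last.index)
    dropped = first.index.symmetric_difference(last.index)
    if len(dropped):
        logger.warning("dropping countries without data in both decades: %s", list(dropped))
    if shared.empty:
        raise ValueError("no country has data in both reference decades")
    return last.loc[shared] - first.loc[shared]


@dataclass
class CovariatePanel:
    """Country-level matrix of the 33 explanatory covariates."""

    data: pd.DataFrame
    period: tuple[int, int]
    mode: str = "mean"
    dropped_countries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = covariate_columns()
        if list(self.data.columns) != expected:
            raise ValueError(
                f"covariate panel must have exactly {len(expected)} columns in canonical order"
            )
        if self.data.isna().to_numpy().any():
            raise ValueError("covariate panel contains missing values after assembly")

    @property
    def countries(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def standardized(self) -> pd.DataFrame:
        """Columns centered and scaled to unit (ddof=1) standard deviation."""
        sd = self.data.std(ddof=1)
        if (sd == 0).any():
            zero = list(sd.index[sd == 0])
            raise ValueError(f"zero-variance covariates: {zero}")
        return (self.data - self.data.mean()) / sd


def _yearly_covariates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Wide (country, year) table of the 30 nutritional covariates, per year."""
    measure_of = {
        "N": "N_kg",
        "P": "P_kg",
        "NP": "NP_ratio",
        "kcal": "kcal",
        "protein": "protein_kg",
        "total_kg": "total_kg",
    }
    wide = profiles.unstack("source_category")
    full_cols = pd.MultiIndex.from_product([list(_PROFILE_COLUMNS), list(SOURCE_CATEGORIES)])
    wide = wide.reindex(columns=full_cols)  # absent sources become NaN -> dropped later
    out = pd.DataFrame(index=wide.index)
    for cat, code in SOURCE_CODES.items():
        for m in MEASURES:
            out[f"{m}_{code}"] = wide[(measure_of[m], cat)]
    # derived terrestrial-animal / vegetable quotient, per measure and year
    for m in MEASURES:
        denom = out[f"{m}_veg"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = out[f"{m}_ta"] / denom
        out[f"{m}_{RATIO_CODE}"] = ratio.where(denom != 0)
    return out


def assemble_covariates(
    profiles: pd.DataFrame,
    socio: pd.DataFrame,
    period: tuple[int, int],
    mode: str = "mean",
) -> CovariatePanel:
    """Assemble the 33-column country panel from intake profiles and controls.

    Covariates (including the ta/veg quotient columns and N:P ratios) are
    formed per year and then period-aggregated: ``mean`` averages over the
    period, ``change`` differences the last and first decade means. Countries
    with any missing covariate (e.g. a zero vegetable denominator) are
    dropped, complete-case, with a warning.
    """
    yearly = _yearly_covariates(profiles)
    soc = socio.set_index(["country", "year"])[list(CONTROL_COLUMNS)]
    yearly = yearly.join(soc, how="inner")
    if yearly.empty:
        raise ValueError("no shared (country, year) keys between profiles and socioeconomic table")

    agg = period_aggregate(yearly, period, mode=mode)
    complete = agg.dropna()
    dropped = sorted(set(agg.index) - set(complete.index))
    if dropped:
        logger.warning("dropping countries with incomplete covariates: %s", dropped)
    if complete.empty:
        raise ValueError("no countries with complete covariates in the period")
    return CovariatePanel(
        data=complete[covariate_columns()], period=period, mode=mode, dropped_countries=dropped
    )
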