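"""Age-standardized mortality/prevalence rates per 100,000.

Direct standardization: the standardized rate is the weighted average of
age-group-specific crude rates, with weights given by a fixed standard
population. The default weighting scheme is the WHO World Standard population
(18 five-year age groups, 85+ open-ended), shipped as a data file; weights are
renormalized to sum to one on load so that rounded published shares are safe.
Any other partition can be supplied as long as it matches the mortality
table's age groups.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CAUSES = ("total", "breast", "cervix", "colon", "lung", "prostate")


def load_standard_population(path=None) -> pd.DataFrame:
    """Load a standard-population weight table (columns age_group, weight).

    Without a path, returns the packaged WHO World Standard weights.
    Weights are renormalized to sum to exactly 1.
    """
    if path is None:
        with resources.files("stoichdiet.data").joinpath("who_world_standard.csv").open() as fh:
            std = pd.read_csv(fh)
    else:
        std = pd.read_csv(path)
    return normalize_standard(std)


def normalize_standard(std: pd.DataFrame) -> pd.DataFrame:
    if not {"age_group", "weight"} <= set(std.columns):
        raise ValueError("standard population needs 'age_group' and 'weight' columns")
    if (std["weight"] < 0).any():
        raise ValueError("standard-population weights must be non-negative")
    total = std["weight"].sum()
    if not np.isclose(total, 1.0, atol=0.05):
        raise ValueError(f"standard-population weights sum to {total:.4f}, expected ~1")
    out = std.copy()
    out["weight"] = out["weight"] / total
    return out


def crude_rate(deaths, population, context: str = "") -> np.ndarray | float:
    """Crude rate per 100,000: 1e5 * deaths / population.

    A stratum with zero population and zero deaths is treated as rate 0 with a
    warning; zero population with positive deaths is an error.
    """
    d = np.asarray(deaths, dtype=float)
    p = np.asarray(population, dtype=float)
    if (d < 0).any() or (p < 0).any():
        raise ValueError(f"negative deaths or population {('(' + context + ')') if context else ''}")
    zero_pop = p == 0
    if (zero_pop & (d > 0)).any():
        raise ZeroDivisionError(
            f"zero population with positive deaths {('(' + context + ')') if context else ''}"
        )
    if zero_pop.any():
        warnings.warn(f"zero-population strata treated as rate 0 {context}".strip())
    out = np.zeros_like(d)
    np.divide(d, p, out=out, where=~zero_pop)
    out *= 1e5
    return out if out.ndim else float(out)


def age_standardized_rate(slice_: pd.DataFrame, std: pd.DataFrame) -> float:
    """Directly age-standardized rate per 100,000 for one country/year/cause.

    ``slice_`` needs columns age_group, deaths, population covering every age
    group of the standard population.
    """
    std = normalize_standard(std)
    merged = std.merge(slice_[["age_group", "deaths", "population"]], on="age_group", how="left")
    missing = merged.loc[merged["deaths"].isna(), "age_group"].tolist()
    if missing:
        raise KeyError(f"age groups missing from mortality slice: {missing}")
    rates = crude_rate(merged["deaths"].to_numpy(), merged["population"].to_numpy())
    return float(np.sum(merged["weight"].to_numpy() * rates))


def standardize_table(mortality: pd.DataFrame, std: pd.DataFrame | None = None) -> pd.DataFrame:
    """Standardize a full mortality/prevalence table.

    Input columns: country, year, cause, age_group, deaths, population.
    Output: one row per (country, year, cause) with standardized_rate and
    crude_rate (both per 100,000).
    """
    if std is None:
        std = load_standard_population()
    std = normalize_standard(std)
    weights = std.set_index("age_group")["weight"]

    required = {"country", "year", "cause", "age_group", "deaths", "population"}
    missing = required - set(mortality.columns)
    if missing:
        raise ValueError(f"mortality table missing columns: {sorted(missing)}")
    if (mortality["deaths"] > mortality["population"]).any():
        raise ValueError("deaths exceed population in some strata")

    df = mortality.copy()
    df["rate"] = crude_rate(df["deaths"].to_numpy(), df["population"].to_numpy())
    df["w"] = df["age_group"].map(weights)
    if df["w"].isna().any():
        unknown = sorted(df.loc[df["w"].isna(), "age_group"].unique())
        raise KeyError(f"age groups not in the standard population: {unknown}")

    grouped = df.groupby(["country", "year", "cause"])
    n_groups = grouped["age_group"].nunique()
    if (n_groups != len(weights)).any():
        bad = n_groups[n_groups != len(weights)].index.tolist()
        raise KeyError(f"incomplete age-group coverage for: {bad[:5]}")

    out = grouped.apply(
        lambda g: pd.Series(
            {
                "standardized_rate": float((g["w"] * g["rate"]).sum()),
                "crude_rate": float(1e5 * g["deaths"].sum() / g["population"].sum()),
            }
        ),
        include_groups=False,
    ).reset_index()
    return out
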