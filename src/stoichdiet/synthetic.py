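"""Synthetic country panels with the structure the analysis assumes.

The generator emulates the statistical shape of the real inputs — food-balance
intake tables, nutrient-concentration databases, socioeconomic indicators and
age-structured mortality counts — so that every downstream stage (intake
aggregation, age standardization, covariance clustering, per-cluster PCA,
spike-and-slab regression and back-mapping) can be tested against a known
ground truth without any external download.

Collinearity design
-------------------
Within each source category, log food-group intakes follow a one-factor
latent model per country with role-specific loadings:

    log intake_{c,g} = log m_g + sigma_x * (lam_g * f_s,c + nu * eps_{c,g})

where f_s,c is the source's latent *level* factor, lam_g scales with
sqrt(block_correlation) times a per-role multiplier, and nu with
sqrt(1 - block_correlation). Each source has food groups stylized to be rich
in one nutrient (an N-rich, a P-rich, an energy-dense and a protein-rich
group, plus balanced fillers), so the six derived covariates per source are
distinguishable yet share the block's factor. Because the N-rich group loads
more heavily on the factor than the P-rich group (composition shifts with
affluence), the aggregated N:P ratio co-moves with its source block instead
of splintering off. The socioeconomic controls load on the
terrestrial-animal level factor (diet and development co-move), so the 33
assembled covariates form five collinear blocks: {terrestrial-animal +
controls}, vegetable, terrestrial/vegetable ratio, aquatic-animal,
alcoholic.

Concentration values are stylized to create identifiable covariate structure;
they are plausible in magnitude but are not nutritionally accurate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .intake import CONTROL_COLUMNS, SOURCE_CATEGORIES, covariate_columns
from .rates import load_standard_population

CANCER_SITES = ("total", "breast", "cervix", "colon", "lung", "prostate")
RESPONSE_NAMES = tuple(
    [f"prevalence_{c}" for c in CANCER_SITES]
    + [f"mortality_{c}" for c in CANCER_SITES]
    + ["le_increase"]
)

#: natural-unit anchors per response kind: (intercept, scale)
RESPONSE_KINDS = {
    "prevalence": (250.0, 40.0),
    "mortality": (150.0, 25.0),
    "le_change": (12.0, 2.0),
    "generic": (0.0, 1.0),
}

_DEFAULT_GROUPS = {
    "terrestrial-animal": 6,
    "vegetable": 6,
    "aquatic-animal": 6,
    "alcoholic": 3,
}

# role cycle: each food group is rich in one trait so that the six derived
# covariates per source are not near-duplicates of one another
_ROLES = ("N", "P", "kcal", "protein", "bal", "bal2")
# level-factor loading multiplier per role: N-rich groups respond more
# strongly to the source's latent level factor than P-rich groups, so the
# aggregated N:P ratio itself co-moves with the factor (composition shifts
# with affluence) while every covariate stays tied to its source block
_LAM_DIR = {"N": 1.55, "P": 0.5, "kcal": 1.05, "protein": 0.75, "bal": 1.0, "bal2": 0.9}

# per-source base concentrations: (N g/kg, P g/kg, protein g/kg, kcal/kg)
_BASE_CONC = {
    "terrestrial-animal": (28.0, 2.0, 170.0, 2000.0),
    "vegetable": (5.0, 0.8, 30.0, 800.0),
    "aquatic-animal": (26.0, 2.2, 160.0, 1200.0),
    "alcoholic": (1.0, 0.15, 5.0, 600.0),
}
# per-source base intake, kg/capita/yr
_BASE_INTAKE = {
    "terrestrial-animal": 40.0,
    "vegetable": 150.0,
    "aquatic-animal": 15.0,
    "alcoholic": 30.0,
}

_DOMINANT_MULT = 6.0
_OFF_MULT = 0.3

# latent-model scale constants (see module docstring): group loadings scale
# with sqrt(block_correlation) (so block_correlation = 0 yields independent
# covariates) and the per-group idiosyncratic noise with
# sqrt(1 - block_correlation); the socioeconomic controls load on the
# terrestrial-animal level factor with sqrt(block_correlation) * _CTRL_SCALE
# (capped below 1).
_LAM_SCALE = 0.85
_NU_SCALE = 0.58
_CTRL_SCALE = 1.03
_CTRL_CAP = 0.96
#: cross-country spread of log intakes, year-to-year jitter, and the
#: amplitude of the country-specific growth trend over the full period
_SIGMA_X = 0.35
_SIGMA_YEAR = 0.05
_TREND_AMP = 0.8


def default_age_groups() -> list[tuple[str, float]]:
    """WHO World Standard age groups with their shares as a default pyramid."""
    std = load_standard_population()
    return [(str(a), float(w)) for a, w in zip(std["age_group"], std["weight"])]


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study conditions."""

    n_countries: int = 40
    years: tuple[int, int] = (1960, 2010)
    n_food_groups_per_source: dict | int = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    source_categories: tuple = SOURCE_CATEGORIES
    block_correlation: float = 0.85
    true_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    age_groups: list[tuple[str, float]] = field(default_factory=default_age_groups)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries <= 0:
            raise ValueError("configuration error: n_countries must be positive")
        y0, y1 = self.years
        if y0 > y1:
            raise ValueError("configuration error: years must be a non-empty range")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("configuration error: block_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("configuration error: noise_sd must be non-negative")
        if tuple(self.source_categories) != SOURCE_CATEGORIES:
            raise ValueError(f"configuration error: source_categories must be {SOURCE_CATEGORIES}")
        if isinstance(self.n_food_groups_per_source, int):
            if self.n_food_groups_per_source <= 0:
                raise ValueError("configuration error: n_food_groups_per_source must be positive")
            self.n_food_groups_per_source = {
                s: self.n_food_groups_per_source for s in SOURCE_CATEGORIES
            }
        else:
            for s in SOURCE_CATEGORIES:
                if self.n_food_groups_per_source.get(s, 0) <= 0:
                    raise ValueError(
                        f"configuration error: n_food_groups_per_source[{s!r}] must be positive"
                    )
        shares = np.array([w for _, w in self.age_groups], dtype=float)
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("configuration error: age_groups shares must sum to 1")
        unknown = sorted(set(self.true_effects) - set(covariate_columns()))
        if unknown:
            raise ValueError(f"configuration error: unknown covariates in true_effects: {unknown}")

    @property
    def country_labels(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n_countries)]


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a generated response."""

    true_effects: dict[str, float]
    linear_predictor: pd.Series
    seed: int


class FoodPanel(NamedTuple):
    """Bundle returned by :func:`generate_food_panel`."""

    intake: pd.DataFrame
    concentrations: list[pd.DataFrame]
    socio: pd.DataFrame
    latents: pd.DataFrame  # country-level latent factors (for diagnostics/tests)


def _roles_for(n_groups: int) -> list[str]:
    return [_ROLES[i % len(_ROLES)] for i in range(n_groups)]


def _concentration_base(source: str, groups: list[str]) -> pd.DataFrame:
    """Stylized per-group concentrations, role-dominant within each source."""
    n0, p0, prot0, kcal0 = _BASE_CONC[source]
    rows = []
    roles = _roles_for(len(groups))
    for i, g in enumerate(groups):
        role = roles[i]
        mult = {r: _OFF_MULT for r in ("N", "P", "protein", "kcal")}
        if role in mult:
            mult[role] = _DOMINANT_MULT
        else:  # balanced fillers
            mult = {r: 1.0 for r in mult}
        tweak = 0.85 + 0.1 * (i % 4)  # mild deterministic spread between groups
        rows.append(
            {
                "food_group": g,
                "n_gram_per_kg": n0 * mult["N"] * tweak,
                "p_gram_per_kg": p0 * mult["P"] * tweak,
                "protein_gram_per_kg": prot0 * mult["protein"] * tweak,
                "kcal_per_kg": kcal0 * mult["kcal"] * tweak,
            }
        )
    return pd.DataFrame(rows)


def generate_food_panel(config: SyntheticConfig) -> FoodPanel:
    """Generate the intake table, concentration databases and controls.

    Deterministic in ``config.seed``: the same configuration yields
    bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.block_correlation
    lam0 = _LAM_SCALE * np.sqrt(rho)
    nu0 = max(_NU_SCALE * np.sqrt(1.0 - rho), 0.05)
    sigma_x = _SIGMA_X
    sigma_year = _SIGMA_YEAR
    trend_amp = _TREND_AMP

    countries = config.country_labels
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    n_c, n_y = len(countries), len(years)
    tgrid = (years - y0) / max(y1 - y0, 1)  # 0..1 over the period

    intake_frames = []
    conc_base_frames = []
    latents = {}
    for source in SOURCE_CATEGORIES:
        G = config.n_food_groups_per_source[source]
        code = source.split("-")[0][:4]
        groups = [f"{code}_g{i + 1}" for i in range(G)]
        conc_base_frames.append(_concentration_base(source, groups))

        f = rng.standard_normal(n_c)  # level factor
        f_tr = rng.standard_normal(n_c)  # growth factor (drives the trend slopes)
        latents[f"f_{source}"] = f

        roles = _roles_for(G)
        lam = np.array([lam0 * _LAM_DIR[r] for r in roles])

        eta = rng.standard_normal((n_c, G))
        eta_tr = rng.standard_normal((n_c, G))
        xi = rng.standard_normal((n_c, n_y, G))

        x = lam[None, :] * f[:, None] + nu0 * eta
        slope = trend_amp * (lam[None, :] * f_tr[:, None] + nu0 * eta_tr)
        logI = (
            np.log(_BASE_INTAKE[source] / G)
            + sigma_x * (x[:, None, :] + slope[:, None, :] * (tgrid[None, :, None] - 0.5))
            + sigma_year * xi
        )
        vals = np.exp(logI)  # (country, year, group)

        frame = pd.DataFrame(
            {
                "country": np.repeat(countries, n_y * G),
                "year": np.tile(np.repeat(years, G), n_c),
                "food_group": np.tile(groups, n_c * n_y),
                "source_category": source,
                "intake_kg_per_capita_yr": vals.ravel(),
            }
        )
        intake_frames.append(frame)

    intake = pd.concat(intake_frames, ignore_index=True)
    conc_base = pd.concat(conc_base_frames, ignore_index=True)

    # two concentration databases jittered around the common base values
    concentrations = []
    for db in ("db_a", "db_b"):
        jitter = np.exp(rng.normal(0.0, 0.05, size=(len(conc_base), 4)))
        tab = conc_base.copy()
        tab[["n_gram_per_kg", "p_gram_per_kg", "protein_gram_per_kg", "kcal_per_kg"]] *= jitter
        tab["database_id"] = db
        concentrations.append(tab)

    # socioeconomic controls co-move with the terrestrial-animal level factor
    f_ta = latents["f_terrestrial-animal"]
    a = min(_CTRL_SCALE * np.sqrt(rho), _CTRL_CAP)
    b = np.sqrt(1.0 - a**2)
    z = {c: a * f_ta + b * rng.standard_normal(n_c) for c in CONTROL_COLUMNS}
    z_le = 0.7 * (a * f_ta + b * rng.standard_normal(n_c)) + 0.3 * rng.standard_normal(n_c)
    le_growth = 8.0 + 2.0 * rng.standard_normal(n_c)
    gdp_growth = 0.5 + 0.2 * rng.standard_normal(n_c)
    le_noise = rng.normal(0.0, 0.3, size=(n_c, n_y))

    rows = {
        "country": np.repeat(countries, n_y),
        "year": np.tile(years, n_c),
        "gdp_pc": np.exp(
            9.0 + 0.6 * np.repeat(z["gdp_pc"], n_y) + np.repeat(gdp_growth, n_y) * np.tile(tgrid, n_c)
        ),
        "hdi": 1.0
        / (1.0 + np.exp(-(0.2 + 0.8 * np.repeat(z["hdi"], n_y) + 0.6 * np.tile(tgrid, n_c)))),
        "median_age": np.clip(
            30.0 + 5.0 * np.repeat(z["median_age"], n_y) + 4.0 * np.tile(tgrid, n_c), 15.0, 52.0
        ),
        "life_expectancy": 62.0
        + 7.0 * np.repeat(z_le, n_y)
        + np.repeat(le_growth, n_y) * np.tile(tgrid, n_c)
        + le_noise.ravel(),
    }
    socio = pd.DataFrame(rows)

    lat = pd.DataFrame(latents, index=pd.Index(countries, name="country"))
    lat["z_dev"] = lat["f_terrestrial-animal"] * a  # development proxy used for age tilts
    return FoodPanel(intake=intake, concentrations=concentrations, socio=socio, latents=lat)


def generate_responses(
    panel,
    config: SyntheticConfig,
    name: str = "response",
    kind: str = "generic",
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Sparse linear response on the standardized covariate panel.

    response = intercept + scale * (sum_j beta_j z_j + eps), eps ~ N(0,
    noise_sd); the configured effects are therefore in covariate-SD units.
    ``kind`` selects natural-unit anchors (prevalence/mortality per 100,000,
    life-expectancy change in years, or a unit-scale ``generic``).
    """
    data = panel.data if hasattr(panel, "data") else panel
    unknown = sorted(set(config.true_effects) - set(data.columns))
    if unknown:
        raise KeyError(f"true_effects name covariates absent from the panel: {unknown}")
    if kind not in RESPONSE_KINDS:
        raise ValueError(f"unknown response kind {kind!r}; options: {sorted(RESPONSE_KINDS)}")
    intercept, scale = RESPONSE_KINDS[kind]

    sd = data.std(ddof=1)
    z = (data - data.mean()) / sd.replace(0.0, 1.0)
    lin = np.zeros(len(data))
    for cov, beta in config.true_effects.items():
        lin = lin + beta * z[cov].to_numpy()

    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    eps = rng.normal(0.0, config.noise_sd, size=len(data)) if config.noise_sd > 0 else 0.0
    y = intercept + scale * (lin + eps)
    resp = pd.DataFrame({name: y}, index=data.index)
    truth = SyntheticTruth(
        true_effects=dict(config.true_effects),
        linear_predictor=pd.Series(intercept + scale * lin, index=data.index, name="linear_predictor"),
        seed=used_seed,
    )
    return resp, truth


def generate_mortality_counts(
    rates_by_age: pd.DataFrame, population_by_age: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Poisson death counts: deaths ~ Poisson(rate * population / 1e5).

    ``rates_by_age`` columns: country, year, cause, age_group, rate;
    ``population_by_age`` columns: country, year, age_group, population.
    """
    if (rates_by_age["rate"] < 0).any():
        raise ValueError("negative rates")
    if (population_by_age["population"] <= 0).any():
        raise ValueError("population must be positive")
    key_r = set(rates_by_age["age_group"])
    key_p = set(population_by_age["age_group"])
    if key_r != key_p:
        raise KeyError(
            f"age-group keys differ between tables: {sorted(key_r ^ key_p)}"
        )
    merged = rates_by_age.merge(population_by_age, on=["country", "year", "age_group"], how="left")
    if merged["population"].isna().any():
        missing = merged.loc[merged["population"].isna(), ["country", "year", "age_group"]]
        raise KeyError(f"population missing for keys like {missing.iloc[0].to_dict()}")
    rng = np.random.default_rng(seed)
    mean = merged["rate"].to_numpy() * merged["population"].to_numpy() / 1e5
    merged["deaths"] = rng.poisson(mean)
    return merged[["country", "year", "cause", "age_group", "deaths", "population"]]


def age_specific_rates(
    target_asr: pd.DataFrame, age_groups: list[tuple[str, float]], gradient: float = 0.25
) -> pd.DataFrame:
    """Expand target age-standardized rates into age-specific rates.

    Relative risks rise exponentially with age-group index (cancer-like) and
    are normalized against the standard weights so that directly
    standardizing the expanded rates returns the target exactly.
    ``target_asr`` columns: country, year, cause, rate.
    """
    labels = [a for a, _ in age_groups]
    weights = np.array([w for _, w in age_groups], dtype=float)
    idx = np.arange(len(labels), dtype=float)
    rr = np.exp(gradient * (idx - idx.mean()))
    rr /= float(weights @ rr)

    base = target_asr.loc[target_asr.index.repeat(len(labels))].reset_index(drop=True)
    base["age_group"] = np.tile(labels, len(target_asr))
    base["rate"] = base["rate"].to_numpy() * np.tile(rr, len(target_asr))
    return base


def synthetic_population(
    config: SyntheticConfig,
    dev_score: pd.Series | None = None,
    total_population: float = 5e6,
    tilt: float = 0.6,
) -> pd.DataFrame:
    """Per country-year-age-group populations with development-tilted pyramids.

    More developed countries (higher ``dev_score``) get older pyramids, so
    crude and standardized rates genuinely differ.
    """
    labels = [a for a, _ in config.age_groups]
    shares = np.array([w for _, w in config.age_groups], dtype=float)
    idx = np.arange(len(labels), dtype=float)
    centered = idx / max(len(labels) - 1, 1) - 0.5

    countries = config.country_labels
    if dev_score is None:
        dev_score = pd.Series(0.0, index=countries)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)

    frames = []
    for c in countries:
        s = shares * np.exp(tilt * float(dev_score.get(c, 0.0)) * centered)
        s /= s.sum()
        pops = np.maximum(np.rint(total_population * s), 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "country": c,
                    "year": np.repeat(years, len(labels)),
                    "age_group": np.tile(labels, len(years)),
                    "population": np.tile(pops, len(years)).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
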