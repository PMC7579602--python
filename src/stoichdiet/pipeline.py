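"""End-to-end driver: covariates -> clusters -> factors -> SSVS -> back-map.

``run_full_model`` reproduces, on any covariate panel and response table, the
coefficient-grid analysis: the 33 covariates are clustered, each cluster is
reduced to its leading eigenvectors, each response is regressed on the factor
scores under the spike-and-slab prior, and the factor coefficients are mapped
back to the covariates through the loadings. ``simulate_study`` manufactures
a full synthetic study (intake tables through standardized mortality rates)
with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic
from .intake import CovariatePanel, assemble_covariates, compute_intake_profile, merge_concentrations
from .rates import load_standard_population, standardize_table
from .reduction import ClusterPartition, FactorSet, cluster_covariates, covariate_distance, extract_factors
from .ssvs import SSVSConfig, SSVSRegression, backmap_coefficients


@dataclass
class CoefficientGrid:
    """Back-mapped covariate x response grid of posterior summaries."""

    table: pd.DataFrame  # long: covariate, response, median, lower, upper, inclusion, significant
    partition: ClusterPartition
    factors: FactorSet

    def matrix(self, value: str = "median") -> pd.DataFrame:
        return self.table.pivot(index="covariate", columns="response", values=value)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None, ax=None):
        """Shaded coefficient-tile figure; non-significant cells are white."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        med = self.matrix("median")
        sig = self.matrix("significant").astype(bool)
        shown = med.where(sig)
        if ax is None:
            fig, ax = plt.subplots(
                figsize=(2.5 + 0.6 * shown.shape[1], 1.0 + 0.3 * shown.shape[0]),
                layout="constrained",
            )
        else:
            fig = ax.figure
        vmax = np.nanmax(np.abs(med.to_numpy())) or 1.0
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("white")
        im = ax.imshow(shown.to_numpy(), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xticks(range(shown.shape[1]), shown.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(shown.shape[0]), shown.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="posterior median (SD units)")
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return ax


def run_full_model(
    panel: CovariatePanel,
    responses: pd.DataFrame,
    config: SSVSConfig | None = None,
    n_eig: int = 3,
    seed: int | None = None,
    k_range=None,
) -> CoefficientGrid:
    """Cluster -> per-cluster PCA -> SSVS per response -> back-map.

    Responses are standardized internally, so back-mapped medians are in
    (response SD) per (covariate SD) units. Each response gets an independent
    MCMC stream derived from ``seed``.
    """
    data = panel.data if hasattr(panel, "data") else panel
    shared = data.index.intersection(responses.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared countries; need at least 10")
    data = data.loc[shared]
    responses = responses.loc[shared]

    dist = covariate_distance(data)
    partition = cluster_covariates(dist, k_range=k_range)
    factors = extract_factors(data, partition, n_eig=n_eig)

    cfg = config or SSVSConfig()
    seeds = np.random.SeedSequence(seed).generate_state(responses.shape[1]) % (2**31)

    rows = []
    for j, resp in enumerate(responses.columns):
        y = responses[resp].to_numpy(dtype=float)
        ysd = y.std(ddof=1)
        if ysd == 0:
            raise ValueError(f"response {resp!r} has zero variance")
        y = (y - y.mean()) / ysd
        model = SSVSRegression(y, factors.scores, config=cfg)
        res = model.fit(seed=int(seeds[j]))
        mapped = backmap_coefficients(res, factors)
        mapped = mapped.reset_index(names="covariate")
        mapped.insert(1, "response", resp)
        rows.append(mapped)

    table = pd.concat(rows, ignore_index=True)
    return CoefficientGrid(table=table, partition=partition, factors=factors)


def build_panel(food_panel, period=None, mode: str = "mean") -> CovariatePanel:
    """Intake tables + concentrations + controls -> 33-column covariate panel."""
    conc = merge_concentrations(food_panel.concentrations)
    profiles = compute_intake_profile(food_panel.intake, conc)
    if period is None:
        years = food_panel.intake["year"]
        period = (int(years.min()), int(years.max()))
    return assemble_covariates(profiles, food_panel.socio, period, mode=mode)


def simulate_study(
    config: synthetic.SyntheticConfig,
    period=None,
    mode: str = "mean",
    mortality_via_counts: bool = True,
):
    """Generate a complete synthetic study with known truth.

    Returns (panel, responses, truths). Prevalence responses and the
    life-expectancy increase are drawn directly on the covariate panel;
    mortality responses are pushed through Poisson age-structured death
    counts and direct age standardization (the same path real data take),
    averaging the yearly standardized rates over the period.
    """
    food = synthetic.generate_food_panel(config)
    panel = build_panel(food, period=period, mode=mode)

    root = np.random.SeedSequence(config.seed)
    streams = root.generate_state(len(synthetic.RESPONSE_NAMES) + 1) % (2**31)

    responses = {}
    truths = {}
    std = load_standard_population()
    pop = None
    for j, name in enumerate(synthetic.RESPONSE_NAMES):
        kind = "prevalence" if name.startswith("prevalence") else (
            "mortality" if name.startswith("mortality") else "le_change"
        )
        resp, truth = synthetic.generate_responses(
            panel, config, name=name, kind=kind, seed=int(streams[j])
        )
        truths[name] = truth
        if kind == "mortality" and mortality_via_counts:
            target = resp[name].clip(lower=1.0)
            y0, y1 = config.years
            years = np.arange(y0, y1 + 1)
            tbl = pd.DataFrame(
                {
                    "country": np.repeat(target.index.to_numpy(), len(years)),
                    "year": np.tile(years, len(target)),
                    "cause": name.removeprefix("mortality_"),
                    "rate": np.repeat(target.to_numpy(), len(years)),
                }
            )
            by_age = synthetic.age_specific_rates(tbl, config.age_groups)
            if pop is None:
                pop = synthetic.synthetic_population(config, dev_score=food.latents["z_dev"])
            counts = synthetic.generate_mortality_counts(by_age, pop, seed=int(streams[-1]) + j)
            std_rates = standardize_table(counts, std)
            observed = std_rates.groupby("country")["standardized_rate"].mean()
            responses[name] = observed.reindex(panel.data.index)
        else:
            responses[name] = resp[name]

    return panel, pd.DataFrame(responses, index=panel.data.index), truths
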