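"""Bayesian linear regression with a stochastic-search variable-selection prior.

Each coefficient beta_j carries a two-component Gaussian mixture prior: a
narrow "spike" N(0, tau0^2) and a diffuse "slab" N(0, tau1^2), mixed by a
latent Bernoulli inclusion indicator gamma_j with prior inclusion probability
p. The residual variance sigma^2 has an inverse-gamma prior. The posterior is
explored by a Gibbs sampler cycling

  (a) beta | gamma, sigma^2, y  ~  N(A^-1 X'y / sigma^2, A^-1),
      A = X'X / sigma^2 + D^-1,  D = diag(tau_{gamma_j}^2)
  (b) gamma_j | beta_j          ~  Bernoulli from the two-component
      normal-mixture posterior odds
  (c) sigma^2 | beta, y         ~  InvGamma(a + n/2, b + RSS/2)

Coefficients of regressors the data judge unimportant are shrunk toward zero
through the spike, and the posterior frequency of gamma_j = 1 measures each
regressor's relevance. In the limit tau0 -> tau1 (or with all indicators
forced to 1) the posterior mean reduces to the ridge estimate
(X'X + sigma^2/tau1^2 I)^-1 X'y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SSVSConfig:
    """Prior and sampler settings for the spike-and-slab regression.

    Defaults assume standardized regressors and a centered (or standardized)
    response: spike sd 0.01 (effectively zero on that scale), slab sd 10
    (diffuse), prior inclusion 0.5 (agnostic), InvGamma(0.01, 0.01) on the
    residual variance.
    """

    spike_sd: float = 0.01
    slab_sd: float = 10.0
    prior_inclusion: float = 0.5
    sigma_prior_shape: float = 0.01
    sigma_prior_scale: float = 0.01
    n_draws: int = 20_000
    n_burn: int = 5_000
    thin: int = 5
    credible_level: float = 0.95
    seed: int | None = None
    force_include: tuple = ()

    def __post_init__(self) -> None:
        if not (0 < self.spike_sd < self.slab_sd):
            raise ValueError("require slab_sd > spike_sd > 0")
        if not (0 < self.prior_inclusion < 1):
            raise ValueError("prior inclusion probability must be in (0, 1)")
        if self.n_draws <= self.n_burn:
            raise ValueError("n_draws must exceed n_burn")
        if self.thin < 1 or self.sigma_prior_shape <= 0 or self.sigma_prior_scale <= 0:
            raise ValueError("invalid sampler settings")
        if not (0 < self.credible_level < 1):
            raise ValueError("credible level must be in (0, 1)")


class SSVSRegression:
    """Spike-and-slab linear model; ``fit`` runs the Gibbs sampler.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector; centered internally.
    exog : DataFrame or array, shape (n, k)
        Regressors; standardized internally by default (coefficients are then
        reported per standard deviation of each regressor).
    config : SSVSConfig, optional
    """

    def __init__(self, endog, exog, config: SSVSConfig | None = None, standardize: bool = True):
        self.config = config or SSVSConfig()
        if isinstance(exog, pd.DataFrame):
            self.exog_names = [str(c) for c in exog.columns]
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{j + 1}" for j in range(X.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("exog must be 2-D with one row per response element")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 observations")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in endog/exog")

        self._y_mean = y.mean()
        self.endog = y - self._y_mean
        self._x_mean = X.mean(axis=0)
        if standardize:
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).any():
                bad = [self.exog_names[j] for j in np.flatnonzero(sd == 0)]
                raise ValueError(f"zero-variance regressors: {bad}")
            self._x_sd = sd
        else:
            self._x_sd = np.ones(X.shape[1])
        self.exog = (X - self._x_mean) / self._x_sd

        fi = set()
        for item in self.config.force_include:
            fi.add(self.exog_names.index(item) if isinstance(item, str) else int(item))
        self._force_include = np.array(sorted(fi), dtype=int)

    def fit(self, seed: int | None = None) -> "SSVSResults":
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        rng = np.random.default_rng(seed)

        X, y = self.exog, self.endog
        n, k = X.shape
        XtX = X.T @ X
        Xty = X.T @ y

        tau2 = np.array([cfg.spike_sd**2, cfg.slab_sd**2])
        log_prior_odds = np.log(cfg.prior_inclusion) - np.log1p(-cfg.prior_inclusion)

        gamma = np.ones(k, dtype=int)
        sigma2 = float(np.var(y)) or 1.0
        beta = np.zeros(k)

        n_keep = (cfg.n_draws - cfg.n_burn) // cfg.thin
        beta_draws = np.empty((n_keep, k))
        gamma_draws = np.empty((n_keep, k), dtype=np.int8)
        sigma2_draws = np.empty(n_keep)

        kept = 0
        for it in range(cfg.n_draws):
            # (a) beta | gamma, sigma2
            A = XtX / sigma2 + np.diag(1.0 / tau2[gamma])
            L = np.linalg.cholesky(A)
            mu = np.linalg.solve(A, Xty / sigma2)
            z = rng.standard_normal(k)
            beta = mu + np.linalg.solve(L.T, z)

            # (b) gamma_j | beta_j: two-component normal mixture posterior
            b2 = beta**2
            log_odds = (
                log_prior_odds
                + 0.5 * b2 * (1.0 / tau2[0] - 1.0 / tau2[1])
                + np.log(cfg.spike_sd / cfg.slab_sd)
            )
            p_incl = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
            gamma = (rng.random(k) < p_incl).astype(int)
            if self._force_include.size:
                gamma[self._force_include] = 1

            # (c) sigma2 | beta, y
            resid = y - X @ beta
            shape = cfg.sigma_prior_shape + 0.5 * n
            scale = cfg.sigma_prior_scale + 0.5 * resid @ resid
            sigma2 = scale / rng.gamma(shape)

            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0 and kept < n_keep:
                beta_draws[kept] = beta
                gamma_draws[kept] = gamma
                sigma2_draws[kept] = sigma2
                kept += 1

        return SSVSResults(
            model=self,
            beta_draws=beta_draws[:kept],
            gamma_draws=gamma_draws[:kept],
            sigma2_draws=sigma2_draws[:kept],
            seed=seed,
        )


@dataclass
class SSVSResults:
    """Posterior draws and summaries from an :class:`SSVSRegression` fit.

    ``beta_draws`` are on the internally standardized regressor scale;
    ``beta_draws_original`` rescales them to the scale of the regressors as
    supplied.
    """

    model: SSVSRegression
    beta_draws: np.ndarray
    gamma_draws: np.ndarray
    sigma2_draws: np.ndarray
    seed: int | None = None
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def beta_draws_original(self) -> np.ndarray:
        return self.beta_draws / self.model._x_sd

    @property
    def params(self) -> pd.Series:
        """Posterior median coefficients (standardized regressor scale)."""
        return pd.Series(np.median(self.beta_draws, axis=0), index=self.exog_names, name="median")

    @property
    def inclusion_probs(self) -> pd.Series:
        """Posterior inclusion frequency of each regressor."""
        return pd.Series(self.gamma_draws.mean(axis=0), index=self.exog_names, name="inclusion")

    def conf_int(self, level: float | None = None, original_scale: bool = False) -> pd.DataFrame:
        """Equal-tailed credible intervals (optionally on the supplied X scale)."""
        level = level if level is not None else self.model.config.credible_level
        alpha = (1.0 - level) / 2.0
        draws = self.beta_draws_original if original_scale else self.beta_draws
        lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.exog_names)

    @property
    def significant(self) -> pd.Series:
        """Whether the equal-tailed credible interval excludes zero."""
        ci = self.conf_int()
        return pd.Series((ci["lower"] > 0) | (ci["upper"] < 0), name="significant")

    @property
    def sigma2_mean(self) -> float:
        return float(self.sigma2_draws.mean())

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "median": self.params,
                "lower": ci["lower"],
                "upper": ci["upper"],
                "inclusion": self.inclusion_probs,
                "significant": self.significant,
            }
        )
        return out

    def __str__(self) -> str:
        cfg = self.model.config
        head = (
            f"SSVS regression: n={self.model.exog.shape[0]}, k={self.model.exog.shape[1]}, "
            f"{len(self.beta_draws)} kept draws "
            f"(spike={cfg.spike_sd}, slab={cfg.slab_sd}, p={cfg.prior_inclusion})\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v: .4f}")


def backmap_coefficients(results: SSVSResults, factors) -> pd.DataFrame:
    """Map factor-level posterior draws back to covariate-level summaries.

    For every MCMC draw, a covariate's effect is the loading-weighted sum of
    its cluster's factor coefficients (coefficients taken on the raw factor
    scale, so the result is the effect per standard deviation of the
    covariate). Regressors in the fit that are not factors (e.g. controls kept
    outside the clustering) pass through unmapped. Summaries are the posterior
    median, the equal-tailed credible interval and the significance flag
    computed on the mapped draws.
    """
    names = results.exog_names
    factor_cols = [c for c in names if c in set(factors.factor_names)]
    passthrough = [c for c in names if c not in set(factors.factor_names)]
    missing = [c for c in factors.factor_names if c not in names]
    if missing:
        raise ValueError(f"factor regressors absent from the posterior: {missing}")

    draws = results.beta_draws_original
    idx = [names.index(c) for c in factor_cols]
    L = factors.loadings[factor_cols].to_numpy()
    mapped = draws[:, idx] @ L.T  # (draws x covariates)

    # a draw "includes" a covariate when any factor of its cluster is in the slab
    gamma_f = results.gamma_draws[:, idx]
    cluster_ids = factors.cluster_of.to_numpy()
    factor_cluster = np.array(
        [factors.cluster_of[factors.loadings[c].abs().idxmax()] for c in factor_cols]
    )
    incl = np.stack(
        [gamma_f[:, factor_cluster == cid].any(axis=1) for cid in cluster_ids], axis=1
    )

    level = results.model.config.credible_level
    alpha = (1.0 - level) / 2.0

    def summarize(d: np.ndarray, inclusion: np.ndarray, index) -> pd.DataFrame:
        lo, hi = np.quantile(d, [alpha, 1.0 - alpha], axis=0)
        med = np.median(d, axis=0)
        return pd.DataFrame(
            {
                "median": med,
                "lower": lo,
                "upper": hi,
                "inclusion": inclusion.mean(axis=0),
                "significant": (lo > 0) | (hi < 0),
            },
            index=index,
        )

    out = summarize(mapped, incl, factors.loadings.index)
    if passthrough:
        pidx = [names.index(c) for c in passthrough]
        extra = summarize(results.beta_draws[:, pidx], results.gamma_draws[:, pidx], passthrough)
        out = pd.concat([out, extra])
    return out
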