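"""Reduced major-axis (standardized major axis) bivariate fits.

The RMA line treats both axes as error-bearing: slope = sign(r) * sd(y)/sd(x)
and the line passes through the centroid (mean x, mean y). The reported
p-value is the two-sided test of the Pearson correlation on n-2 degrees of
freedom; a permutation p-value is available for small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RMAFit:
    """Reduced major-axis fit results."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    degenerate_sign: bool = False

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        note = " (r = 0: slope sign set positive by convention)" if self.degenerate_sign else ""
        return (
            f"RMA fit (n={self.n}): y = {self.intercept:.4g} + {self.slope:.4g} x, "
            f"r = {self.r:.3f}, p = {self.p_value:.3g}{note}"
        )


def rma_fit(x, y) -> RMAFit:
    """Fit a reduced major-axis line to paired observations."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in x/y")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")

    r, p = stats.pearsonr(x, y)
    degenerate = r == 0.0
    if degenerate:
        warnings.warn("r is exactly 0; RMA slope sign set positive by convention")
    sign = 1.0 if degenerate else float(np.sign(r))
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return RMAFit(
        slope=float(slope), intercept=intercept, r=float(r), p_value=float(p), n=int(n),
        degenerate_sign=bool(degenerate),
    )


def permutation_pvalue(x, y, n_perm: int = 10_000, seed: int | None = None) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    r_obs = abs(stats.pearsonr(x, y)[0])
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    hits = 0
    for _ in range(n_perm):
        r = abs(xc @ rng.permutation(yc)) / denom
        hits += r >= r_obs - 1e-15
    return (hits + 1) / (n_perm + 1)
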