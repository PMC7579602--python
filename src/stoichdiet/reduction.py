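"""Collinearity-aware dimension reduction of the covariate panel.

Covariates are clustered by their correlation structure (distance
1 - |Pearson r|, average-linkage agglomeration), the number of clusters is
chosen with the Kelley–Gardner–Sutcliffe penalty, and each cluster is reduced
to its leading principal components. The retained eigenvector loadings allow
regression coefficients estimated on the factors to be mapped back to the
original covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def covariate_distance(panel) -> pd.DataFrame:
    """Sign-blind correlation distance 1 - |r| between covariate columns.

    A negatively correlated covariate is just as redundant as a positively
    correlated one for dimension reduction, hence the absolute value.
    """
    data = panel.data if hasattr(panel, "data") else panel
    if len(data) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    sd = data.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance covariates: {list(sd.index[sd == 0])}")
    corr = data.corr()
    dist = 1.0 - corr.abs()
    np.fill_diagonal(dist.values, 0.0)
    return dist


@dataclass
class ClusterPartition:
    """Covariate clustering with the Kelley-selected number of clusters."""

    labels: pd.Series  # covariate name -> cluster id (1..k)
    linkage: np.ndarray
    k: int
    kelley_scores: dict[int, float]

    @property
    def clusters(self) -> dict[int, list[str]]:
        return {int(c): list(self.labels.index[self.labels == c]) for c in sorted(self.labels.unique())}


def _cut_spread(dmat: np.ndarray, assignment: np.ndarray) -> float:
    """Mean over multi-member clusters of the mean pairwise within distance."""
    spreads = []
    for cid in np.unique(assignment):
        idx = np.flatnonzero(assignment == cid)
        if len(idx) < 2:
            continue
        block = dmat[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        spreads.append(block[iu].mean())
    if not spreads:
        warnings.warn("all clusters are singletons at this cut; spread taken as 0")
        return 0.0
    return float(np.mean(spreads))


def kelley_scores(Z: np.ndarray, dmat: np.ndarray, ks) -> dict[int, float]:
    """Kelley penalty over a range of cluster counts (lower is better).

    At each candidate cut k the average within-cluster spread (mean over
    multi-member clusters of the mean pairwise distance) is computed, then
    normalized onto [1, n-1] and the cluster count k is added. The
    normalization is anchored between the smallest candidate spread and the
    trivial one-cluster spread (the mean pairwise distance of the whole set),
    so the score measures how much of the total spread a cut leaves
    unresolved; without the anchor, cleanly separated data - where every
    candidate cut is already tight - would have meaninglessly small spread
    differences amplified to the full scale and the penalty would over-split.
    """
    n = dmat.shape[0]
    ks = sorted(set(int(k) for k in ks))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"cluster counts must lie in [2, {n - 1}]")
    spreads = {}
    for k in ks:
        assignment = fcluster(Z, t=k, criterion="maxclust")
        spreads[k] = _cut_spread(dmat, assignment)
    vals = np.array([spreads[k] for k in ks])
    lo = vals.min()
    hi = max(_cut_spread(dmat, np.ones(n, dtype=int)), vals.max())
    if hi > lo:
        norm = 1.0 + (n - 2) * (vals - lo) / (hi - lo)
    else:
        norm = np.ones_like(vals)
    return {k: float(nv + k) for k, nv in zip(ks, norm)}


def kelley_index(Z: np.ndarray, dmat: np.ndarray, k: int, ks=None) -> float:
    """Kelley penalty at one k (normalized across ``ks``, default 2..n-1)."""
    n = dmat.shape[0]
    if ks is None:
        ks = range(2, n)
    return kelley_scores(Z, dmat, ks)[int(k)]


def cluster_covariates(distances: pd.DataFrame, k_range=None) -> ClusterPartition:
    """Average-linkage hierarchical clustering with Kelley-selected k.

    Ties in the Kelley score are broken toward the smaller cluster count.
    """
    dmat = np.asarray(distances, dtype=float)
    names = list(distances.index)
    n = dmat.shape[0]
    if not np.allclose(dmat, dmat.T) or not np.allclose(np.diag(dmat), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.all(dmat == 0):
        raise ValueError("degenerate all-zero distance matrix")
    if k_range is None:
        k_range = range(2, n)
    Z = linkage(squareform(dmat, checks=False), method="average")
    scores = kelley_scores(Z, dmat, k_range)
    best_k = min(scores, key=lambda k: (scores[k], k))
    labels = pd.Series(fcluster(Z, t=best_k, criterion="maxclust"), index=names, name="cluster")
    return ClusterPartition(labels=labels, linkage=Z, k=int(labels.nunique()), kelley_scores=scores)


@dataclass
class FactorSet:
    """Per-cluster principal components with loadings for back-mapping.

    ``loadings`` is a (covariates x factors) matrix, zero outside a factor's
    own cluster, so that ``scores = standardized_data @ loadings`` and a
    draw of factor coefficients maps to covariate effects as
    ``loadings @ beta_factors``.
    """

    loadings: pd.DataFrame
    eigenvalues: dict[int, np.ndarray]
    variance_fraction: dict[int, float]
    scores: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    cluster_of: pd.Series

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)


def extract_factors(panel, partition: ClusterPartition, n_eig: int = 3) -> FactorSet:
    """Per-cluster PCA of the standardized covariates.

    Retains min(n_eig, cluster size) leading eigenvectors per cluster;
    eigenvector signs are fixed by making each vector's largest-magnitude
    loading positive. Warns when a cluster's retained variance fraction is
    below 0.90.
    """
    data = panel.data if hasattr(panel, "data") else panel
    if len(data) < 2:
        raise ValueError("need at least 2 rows for PCA")
    means = data.mean()
    sds = data.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"zero-variance covariates: {list(sds.index[sds == 0])}")
    Z = (data - means) / sds

    loading_cols: dict[str, pd.Series] = {}
    eigenvalues: dict[int, np.ndarray] = {}
    variance_fraction: dict[int, float] = {}
    for cid, members in partition.clusters.items():
        if not members:
            raise ValueError(f"cluster {cid} is empty")
        block = Z[members].to_numpy()
        corr = block.T @ block / (len(block) - 1)
        vals, vecs = np.linalg.eigh(corr)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        r = min(n_eig, len(members))
        for j in range(r):
            v = vecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            loading_cols[f"c{cid}_e{j + 1}"] = pd.Series(v, index=members)
        eigenvalues[cid] = vals
        frac = float(vals[:r].sum() / vals.sum())
        variance_fraction[cid] = frac
        if frac < 0.90:
            warnings.warn(
                f"cluster {cid}: top-{r} eigenvectors capture only {frac:.1%} of variance"
            )

    loadings = pd.DataFrame(loading_cols, index=data.columns).fillna(0.0)
    scores = pd.DataFrame(Z.to_numpy() @ loadings.to_numpy(), index=data.index, columns=loadings.columns)
    return FactorSet(
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_fraction=variance_fraction,
        scores=scores,
        means=means,
        sds=sds,
        cluster_of=partition.labels.copy(),
    )


def compute_vif(X) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2) per column.

    R^2 comes from regressing each column (with intercept) on all others.
    Exactly collinear columns are reported as infinite with a warning.
    """
    data = X.data if hasattr(X, "data") else X
    df = pd.DataFrame(data)
    n, p = df.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    if n <= p:
        raise ValueError("need more rows than columns")
    M = df.to_numpy(dtype=float)
    out = {}
    for j, col in enumerate(df.columns):
        y = M[:, j]
        others = np.delete(M, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            raise ValueError(f"zero-variance column {col!r}")
        r2 = 1.0 - resid @ resid / sst
        if 1.0 - r2 < 1e-12:
            warnings.warn(f"column {col!r} is exactly collinear with the others; VIF infinite")
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
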