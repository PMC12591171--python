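"""Spatial diagnostics and constraint analysis.

Moran's I on model residuals detects spatial clustering of prediction
errors (null expectation -1/(n-1); significance via the normal
approximation, optionally a permutation test). The empirical semivariogram
uses the classical Matheron estimator. Constraint analysis ranks
covariates by how much of the additional-storage map each explains alone
(a smooth univariate fit, since the relationships are curved), and traces
the partial dependence of an ensemble fit on mean annual temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .core_data import CovariateGrid


@dataclass
class MoranResult:
    I: float
    expected: float          # -1/(n-1)
    variance: float
    z: float
    p_value: float           # two-sided, normal approximation
    p_permutation: float | None
    n: int
    weights: str


def _weight_matrix(coords: np.ndarray, scheme: str, k: int, cutoff: float | None,
                   seed: int = 0) -> np.ndarray:
    """Row-standardized spatial weights; duplicate coordinates are jittered
    deterministically by 1e-9 of the coordinate span."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    uniq = np.unique(coords, axis=0)
    if len(uniq) < n:
        rng = np.random.default_rng(seed)
        span = max(coords.max() - coords.min(), 1.0)
        coords = coords + rng.normal(0, 1e-9 * span, size=coords.shape)
    if scheme == "knn":
        tree = cKDTree(coords)
        _, idx = tree.query(coords, k=min(k, n - 1) + 1)
        W = np.zeros((n, n))
        for i in range(n):
            for j in idx[i][1:]:
                W[i, j] = 1.0
    elif scheme == "idw":
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        W = 1.0 / d
        if cutoff is not None:
            W[d > cutoff] = 0.0
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


def morans_i(residuals: np.ndarray, coords: np.ndarray, scheme: str = "knn",
             k: int = 8, cutoff: float | None = None,
             n_permutations: int = 0, seed: int = 0) -> MoranResult:
    """Global Moran's I of ``residuals`` at ``coords`` (n x 2).

    Weights are row-standardized (default: k-nearest neighbours, k=8).
    Invariant to adding a constant to, or uniformly rescaling, the
    residuals. Raises if the residuals have zero variance.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero residual variance: Moran's I undefined")
    W = _weight_matrix(np.asarray(coords), scheme, k, cutoff, seed=seed)
    s0 = W.sum()
    I = float(n / s0 * (z @ W @ z) / denom)
    expected = -1.0 / (n - 1)

    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    var = ((n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1))) - expected**2
    zscore = (I - expected) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(zscore))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_permutations)
        for b in range(n_permutations):
            zp = rng.permutation(z)
            sims[b] = n / s0 * (zp @ W @ zp) / denom
        p_perm = float((1 + np.sum(np.abs(sims - expected) >= abs(I - expected)))
                       / (1 + n_permutations))
    label = f"{scheme}(k={k})" if scheme == "knn" else f"idw(cutoff={cutoff})"
    return MoranResult(I=I, expected=expected, variance=float(var),
                       z=float(zscore), p_value=float(p),
                       p_permutation=p_perm, n=n, weights=label)


@dataclass
class Variogram:
    lag_centers: np.ndarray
    semivariance: np.ndarray     # NaN for empty bins
    counts: np.ndarray


def semivariogram(values: np.ndarray, coords: np.ndarray, n_bins: int = 12,
                  max_lag: float | None = None) -> Variogram:
    """Empirical Matheron semivariogram: gamma(h) = mean[(v_i - v_j)^2] / 2
    over point pairs in each distance bin."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 observations")
    d = pdist(coords)
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = float(d.max())
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    which = np.digitize(d, edges[1:-1], right=False)
    inside = d <= max_lag
    for b in range(n_bins):
        m = inside & (which == b)
        counts[b] = int(m.sum())
        if counts[b] > 0:
            gamma[b] = 0.5 * dv2[m].mean()
    return Variogram(lag_centers=centers, semivariance=gamma, counts=counts)


@dataclass
class ConstraintResult:
    ranking: pd.DataFrame                 # covariate, r2 — sorted descending
    partial_dependence: pd.DataFrame      # mat grid vs predicted additional


def constraint_analysis(additional_map: np.ndarray, grid: CovariateGrid,
                        covariates: list[str] | None = None,
                        seed: int = 0) -> ConstraintResult:
    """Which covariates constrain additional storage, and how MAT acts.

    Per covariate: R^2 of a quadratic univariate fit of cell-level
    additional storage (constant covariates are skipped). The partial
    dependence of a random-forest fit on MAT shows the direction of the
    climate constraint.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import partial_dependence

    covariates = covariates or ["mat", "ai", "npp", "elevation", "ph",
                                "clay_silt", "mineral"]
    y = np.asarray(additional_map, dtype=float).ravel()
    ok = ~np.isnan(y)
    y = y[ok]
    rows = []
    X = {}
    for c in covariates:
        v = grid.layer(c).ravel()[ok].astype(float)
        X[c] = v
        if np.ptp(v) == 0:
            continue
        vz = (v - v.mean()) / v.std()   # standardize for conditioning
        deg = 2 if len(np.unique(v)) > 2 else 1
        coef = np.polyfit(vz, y, deg=deg)
        resid = y - np.polyval(coef, vz)
        sst = ((y - y.mean()) ** 2).sum()
        rows.append({"covariate": c, "r2": float(1 - (resid**2).sum() / sst)})
    ranking = (pd.DataFrame(rows).sort_values("r2", ascending=False)
               .reset_index(drop=True))

    Xm = pd.DataFrame(X)
    rf = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    rf.fit(Xm, y)
    pd_res = partial_dependence(rf, Xm, features=["mat"], kind="average",
                                grid_resolution=25)
    curve = pd.DataFrame({"mat": pd_res["grid_values"][0],
                          "additional": pd_res["average"][0]})
    return ConstraintResult(ranking=ranking, partial_dependence=curve)
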