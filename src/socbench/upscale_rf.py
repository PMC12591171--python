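"""Ensemble upscaling of MAOC/POC concentrations to covariate grids.

Learner comparison uses tenfold cross-validation with identical fold
assignment for every candidate. The final upscaler is a random forest on
the ln-concentration (default 1000 trees) with permutation feature
importance on held-out data, normalized to sum to one. Map uncertainty
comes from refitting on random 70% subsamples (without replacement by
default) and taking the per-cell mean and empirical 5%/95% quantiles
across replicates. Back-transform to the concentration scale is a plain
exponential (no smearing correction) throughout the package.

Conditional quantiles use the classical quantile-regression-forest
construction: each query point receives the leaf-co-occurrence weights of
the training responses, and quantiles are read off the weighted empirical
CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .core_data import CovariateGrid, Dataset, FOREST_CODES

#: predictor set used for upscaling (sample depth enters as both bounds)
PREDICTORS = ["mat", "ai", "npp", "elevation", "clay_silt", "ph",
              "depth_upper", "depth_bottom", "mineral", "type"]


def design_matrix(ds: Dataset, response: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric predictor matrix and ln-response vector (missing rows drop)."""
    df = ds.records.copy()
    df["mineral"] = (df["mineral_class"] == "high_activity").astype(float)
    df["type"] = (df["forest_type"] == "planted").astype(float)
    sub = df.dropna(subset=PREDICTORS + [response])
    sub = sub[sub[response] > 0]
    return sub[PREDICTORS].astype(float), np.log(sub[response].to_numpy(dtype=float))


def default_learners(seed: int = 0, n_trees: int = 300) -> dict:
    """The five standard learners entered in the CV comparison."""
    return {
        "random_forest": RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1),
        "support_vector_machine": make_pipeline(
            StandardScaler(), SVR(C=10.0, epsilon=0.05)),
        "linear_regression": LinearRegression(),
        "neural_network": make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(64, 32), max_iter=800,
                         random_state=seed)),
        "regression_tree": DecisionTreeRegressor(
            random_state=seed, min_samples_leaf=5),
    }


@dataclass
class CVReport:
    table: pd.DataFrame          # learner, rmse, r2 — sorted by rmse
    winner: str
    folds: int
    seed: int


def compare_learners(ds: Dataset, response: str, learners: dict | None = None,
                     folds: int = 10, seed: int = 0) -> CVReport:
    """K-fold CV of several learners with shared fold assignment."""
    X, y = design_matrix(ds, response)
    if len(X) < folds:
        raise ValueError(f"need at least {folds} records, got {len(X)}")
    if np.var(y) < 1e-12:
        raise ValueError("response has zero variance")
    learners = learners or default_learners(seed=seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    rows = []
    for name, est in learners.items():
        pred = np.empty_like(y)
        for train, test in splits:
            m = clone(est)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X.iloc[train], y[train])
            pred[test] = m.predict(X.iloc[test])
        rows.append({"learner": name,
                     "rmse": float(np.sqrt(mean_squared_error(y, pred))),
                     "r2": float(r2_score(y, pred))})
    table = pd.DataFrame(rows).sort_values("rmse").reset_index(drop=True)
    return CVReport(table=table, winner=table.loc[0, "learner"],
                    folds=folds, seed=seed)


def cv_metrics(ds: Dataset, response: str, folds: int = 10, seed: int = 0,
               n_trees: int = 300) -> dict:
    """Tenfold-CV RMSE and R^2 of the random-forest upscaler alone."""
    rep = compare_learners(
        ds, response,
        learners={"random_forest": RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1)},
        folds=folds, seed=seed)
    row = rep.table.iloc[0]
    return {"rmse": float(row["rmse"]), "r2": float(row["r2"])}


@dataclass
class FittedUpscaler:
    model: RandomForestRegressor
    response: str
    predictors: list[str]
    n_trees: int
    seed: int
    importances: pd.Series       # normalized to sum to 1
    oob_r2: float
    X_train: pd.DataFrame = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)


def fit_upscaler(ds: Dataset, response: str, n_trees: int = 1000,
                 seed: int = 0, importance_repeats: int = 5) -> FittedUpscaler:
    """Fit the conditional-mean forest and permutation importances.

    The forest is trained on all rows; importances come from permuting each
    predictor on a held-out quarter of the data against a forest trained on
    the remaining three quarters (so they are not optimistic in-sample
    scores). Negative importances are clipped to zero before normalizing.
    """
    X, y = design_matrix(ds, response)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                               oob_score=True, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    cut = max(1, int(0.75 * len(X)))
    tr, ev = idx[:cut], idx[cut:]
    side = RandomForestRegressor(n_estimators=min(n_trees, 300),
                                 random_state=seed, n_jobs=1)
    side.fit(X.iloc[tr], y[tr])
    perm = permutation_importance(side, X.iloc[ev], y[ev],
                                  n_repeats=importance_repeats,
                                  random_state=seed)
    imp = np.clip(perm.importances_mean, 0.0, None)
    constant = X.nunique().to_numpy() <= 1
    if constant.any():
        warnings.warn(f"constant predictor(s): {list(X.columns[constant])}")
        imp[constant] = 0.0
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    return FittedUpscaler(model=rf, response=response,
                          predictors=list(X.columns), n_trees=n_trees,
                          seed=seed, importances=pd.Series(imp, index=X.columns),
                          oob_r2=float(rf.oob_score_), X_train=X, y_train=y)


def grid_features(grid: CovariateGrid, forest_type: str = "asis",
                  depth: tuple[float, float] = (0.0, 20.0)
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-forest-cell feature matrix for grid prediction.

    ``forest_type`` is ``"asis"`` (use the mask), ``"natural"`` or
    ``"planted"`` (counterfactual forcing). Returns (features, flat boolean
    forest-cell mask). Maps represent a sample spanning ``depth`` cm.
    """
    cells = grid.forest_cells().ravel()
    t_asis = (grid.forest_mask.ravel()[cells] == FOREST_CODES["planted"]).astype(float)
    t = {"asis": t_asis,
         "natural": np.zeros_like(t_asis),
         "planted": np.ones_like(t_asis)}[forest_type]
    n = int(cells.sum())
    cols = {
        "mat": grid.mat.ravel()[cells], "ai": grid.ai.ravel()[cells],
        "npp": grid.npp.ravel()[cells], "elevation": grid.elevation.ravel()[cells],
        "clay_silt": grid.clay_silt.ravel()[cells], "ph": grid.ph.ravel()[cells],
        "depth_upper": np.full(n, depth[0]), "depth_bottom": np.full(n, depth[1]),
        "mineral": grid.mineral.ravel()[cells].astype(float), "type": t,
    }
    return pd.DataFrame(cols)[PREDICTORS], cells


def predict_concentration(fit: FittedUpscaler, grid: CovariateGrid,
                          forest_type: str = "asis",
                          depth: tuple[float, float] = (0.0, 20.0)) -> np.ndarray:
    """Back-transformed concentration map (g C kg^-1); NaN off-forest."""
    feats, cells = grid_features(grid, forest_type, depth)
    out = np.full(grid.shape[0] * grid.shape[1], np.nan)
    out[cells] = np.exp(fit.model.predict(feats))
    return out.reshape(grid.shape)


def bootstrap_models(ds: Dataset, response: str, B: int = 100,
                     frac: float = 0.70, seed: int = 0, n_trees: int = 100,
                     with_replacement: bool = False, calibrate: bool = True,
                     calibration_depth: float | None = 20.0):
    """Yield B ``(forest, scale)`` pairs, each fit on a ``frac`` subsample.

    Subsampling is without replacement by default (a 70% random sample);
    set ``with_replacement`` for a classical bootstrap of the same size.

    ``scale`` is a per-forest-type ratio back-transform calibration: for
    each type, the mean observed concentration on the replicate's held-out
    rows of that type divided by the mean of its back-transformed
    predictions there (keys ``"natural"``, ``"planted"``). Multiplying
    exp(prediction) by the factor of the type being predicted removes the
    aggregate inflation that exponentiating noisy ln-scale predictions
    otherwise produces (a stratified ratio/smearing correction for
    lognormal responses) -- including its type asymmetry, which matters for
    counterfactual differences; integrated stocks then target the
    mean-concentration scale. Calibration rows are restricted to samples
    whose bottom depth equals ``calibration_depth`` (the depth maps are
    predicted at) when enough such rows exist, so that attenuation of the
    sampling-depth effect cancels at the deployment depth. With
    ``calibrate=False`` both factors are 1.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    X, y = design_matrix(ds, response)
    n = len(X)
    m = max(2, int(round(frac * n)))
    ss = np.random.SeedSequence([seed, 11])
    child_seeds = ss.generate_state(2 * B)
    for b in range(B):
        rng = np.random.default_rng(child_seeds[2 * b])
        if with_replacement:
            idx = rng.choice(n, size=m, replace=True)
            held = np.setdiff1d(np.arange(n), idx)
        else:
            perm = rng.permutation(n)
            idx, held = perm[:m], perm[m:]
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   random_state=int(child_seeds[2 * b + 1] % (2**31)),
                                   n_jobs=1)
        rf.fit(X.iloc[idx], y[idx])
        scale = {"natural": 1.0, "planted": 1.0}
        if calibrate and len(held) > 0:
            if calibration_depth is not None:
                at_depth = held[np.isclose(
                    X["depth_bottom"].to_numpy()[held], calibration_depth)]
                if len(at_depth) >= 40:
                    held = at_depth
            pred = np.exp(rf.predict(X.iloc[held]))
            obs = np.exp(y[held])
            t_held = X["type"].to_numpy()[held]
            for name, code in (("natural", 0.0), ("planted", 1.0)):
                sel = t_held == code
                if sel.sum() >= 10 and pred[sel].mean() > 0:
                    scale[name] = float(obs[sel].mean() / pred[sel].mean())
        yield rf, scale


@dataclass
class BootstrapMaps:
    mean: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    B: int
    seed: int
    replicate_stack: np.ndarray = field(repr=False, default=None)  # (B, ny, nx)


def bootstrap_predict(ds: Dataset, grid: CovariateGrid, response: str,
                      B: int = 100, frac: float = 0.70, seed: int = 0,
                      n_trees: int = 100, forest_type: str = "asis",
                      depth: tuple[float, float] = (0.0, 20.0),
                      with_replacement: bool = False, calibrate: bool = True,
                      keep_stack: bool = False) -> BootstrapMaps:
    """Per-cell mean and empirical 5%/95% quantiles over B refits.

    Quantiles are linear-interpolated empirical quantiles across replicate
    predictions. Non-forest cells carry NaN, never zero. The q05/q95 band
    is widened (never narrowed) to contain the replicate mean, so the
    mean-within-band invariant holds exactly.
    """
    feats, cells = grid_features(grid, forest_type, depth)
    stack = np.empty((B, int(cells.sum())))
    models = bootstrap_models(ds, response, B=B, frac=frac, seed=seed,
                              n_trees=n_trees,
                              with_replacement=with_replacement,
                              calibrate=calibrate)
    t = feats["type"].to_numpy()
    for b, (rf, scale) in enumerate(models):
        s = np.where(t == 1.0, scale["planted"], scale["natural"])
        stack[b] = s * np.exp(rf.predict(feats))

    def to_map(v):
        out = np.full(cells.shape, np.nan)
        out[cells] = v
        return out.reshape(grid.shape)

    mean = stack.mean(axis=0)
    q05 = np.minimum(np.percentile(stack, 5, axis=0), mean)
    q95 = np.maximum(np.percentile(stack, 95, axis=0), mean)
    full = None
    if keep_stack:
        full = np.full((B,) + cells.shape, np.nan)
        full[:, cells] = stack
        full = full.reshape((B,) + tuple(grid.shape))
    return BootstrapMaps(mean=to_map(mean), q05=to_map(q05), q95=to_map(q95),
                         B=B, seed=seed, replicate_stack=full)


def residual_table(fit: FittedUpscaler, ds: Dataset) -> pd.DataFrame:
    """Out-of-bag residuals with site coordinates, for spatial diagnostics.

    OOB predictions avoid in-sample optimism: each site is predicted only
    by trees that did not see it.
    """
    df = ds.records.copy()
    df["mineral"] = (df["mineral_class"] == "high_activity").astype(float)
    df["type"] = (df["forest_type"] == "planted").astype(float)
    sub = df.dropna(subset=PREDICTORS + [fit.response])
    sub = sub[sub[fit.response] > 0]
    oob = fit.model.oob_prediction_
    resid = np.log(sub[fit.response].to_numpy(dtype=float)) - oob
    return pd.DataFrame({"site_id": sub["site_id"].to_numpy(),
                         "lon": sub["lon"].to_numpy(),
                         "lat": sub["lat"].to_numpy(),
                         "residual": resid})


class QuantileForest:
    """Quantile regression forest on the ln-concentration scale.

    A standard random forest is grown on (X, ln y); for a query point the
    training responses are weighted by leaf co-occurrence (per tree,
    1/leaf-size for co-resident training points, averaged over trees) and
    conditional quantiles are read from the weighted empirical CDF
    (smallest response whose cumulative weight reaches q). Monotonicity in
    q is automatic.
    """

    def __init__(self, n_trees: int = 200, seed: int = 0,
                 min_samples_leaf: int = 5):
        self.n_trees = n_trees
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self._rf = None

    def fit(self, X, y) -> "QuantileForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._rf = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed,
            min_samples_leaf=self.min_samples_leaf, n_jobs=1)
        self._rf.fit(X, y)
        order = np.argsort(y, kind="stable")
        self._y_sorted = y[order]
        # (n_train, T) leaf ids, rows re-ordered by ascending response
        self._train_leaves = self._rf.apply(X)[order]
        return self

    def predict_quantiles(self, X, quantiles) -> np.ndarray:
        """(n_query, n_quantiles) conditional quantiles of ln y."""
        qs = np.asarray(quantiles, dtype=float)
        if ((qs <= 0) | (qs >= 1)).any():
            raise ValueError("quantiles must lie strictly inside (0, 1)")
        X = np.asarray(X, dtype=float)
        query_leaves = self._rf.apply(X)          # (n_query, T)
        n_train = self._train_leaves.shape[0]
        n_query = X.shape[0]
        W = np.zeros((n_query, n_train))
        for t in range(self._train_leaves.shape[1]):
            tl = self._train_leaves[:, t]
            ql = query_leaves[:, t]
            # leaf sizes in this tree
            leaves, counts = np.unique(tl, return_counts=True)
            size = dict(zip(leaves.tolist(), counts.tolist()))
            inv = np.array([1.0 / size[l] for l in tl])
            W += (tl[None, :] == ql[:, None]) * inv[None, :]
        W /= self._train_leaves.shape[1]
        cum = np.cumsum(W, axis=1)
        cum /= cum[:, -1:]
        out = np.empty((n_query, len(qs)))
        for j, q in enumerate(qs):
            idx = np.argmax(cum >= q - 1e-12, axis=1)
            out[:, j] = self._y_sorted[idx]
        return out


def fit_quantile_forest(ds: Dataset, response: str, n_trees: int = 200,
                        seed: int = 0) -> QuantileForest:
    """Fit a quantile forest on the full observation table."""
    X, y = design_matrix(ds, response)
    return QuantileForest(n_trees=n_trees, seed=seed).fit(X.to_numpy(), y)
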