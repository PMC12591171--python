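"""Mixed-effects interaction models for ln(MAOC) / ln(POC).

The model is a Gaussian linear mixed model on the natural-log concentration
with a study-level random intercept:

    ln y = b0 + sum_j b_j z_j + T b_T + sum_k g_k (T * z_k) + u_study + eps

where z_j are standardized covariates and T is the plantation dummy
(planted = 1, natural = 0). Fixed-effect selection uses backward elimination
on AIC under maximum likelihood; the final reported fit uses REML.
Wald (normal-approximation) confidence intervals and p-values are reported;
variance explained follows the marginal/conditional pseudo-R^2 convention
for mixed models (fixed effects alone vs fixed plus random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import Dataset

DEFAULT_COVARIATES = ["mat", "ai", "npp", "elevation", "ph", "clay_silt", "mineral"]
DEFAULT_INTERACTIONS = ["mat", "ai", "npp", "elevation", "ph", "clay_silt", "mineral"]


@dataclass
class MixedModelSpec:
    """Fixed-effect structure of one mixed model.

    ``interactions`` lists covariates whose product with the plantation
    dummy enters the model; marginality requires each to appear in
    ``covariates`` too, and ``include_type`` to be True.
    """

    response: str = "maoc"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    include_type: bool = True
    interactions: list[str] = field(default_factory=lambda: list(DEFAULT_INTERACTIONS))
    grouping: str = "study_id"
    standardize: bool = True
    #: per-covariate (mean, sd) actually used; filled at fit time
    standardization: dict = field(default_factory=dict)

    def validate(self) -> "MixedModelSpec":
        for c in self.interactions:
            if c not in self.covariates:
                raise ValueError(f"interaction with {c!r} lacks its main effect")
        if self.interactions and not self.include_type:
            raise ValueError("type x covariate interactions require the type term")
        return self

    def term_names(self) -> list[str]:
        names = ["intercept"] + list(self.covariates)
        if self.include_type:
            names.append("type")
        names += [f"type:{c}" for c in self.interactions]
        return names


@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    coefficients: pd.DataFrame        # estimate, se, ci_low, ci_high, p per term
    coefficients_raw: pd.DataFrame    # same terms on per-raw-unit scale
    cov_params: pd.DataFrame
    var_study: float
    var_resid: float
    loglike: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    n_used: int
    n_dropped: int
    converged: bool
    reml: bool


def _encode_mineral(series: pd.Series) -> np.ndarray:
    return (series == "high_activity").astype(float).to_numpy()


def _design(ds: Dataset, spec: MixedModelSpec):
    """Assemble endog/exog/groups; rows with any missing model column drop."""
    cols = [spec.response, spec.grouping, "forest_type"] + [
        c for c in spec.covariates if c != "mineral"]
    df = ds.records.copy()
    df["mineral"] = _encode_mineral(df["mineral_class"])
    needed = set(cols) | set(spec.covariates)
    sub = df.dropna(subset=[c for c in needed if c in df.columns])
    sub = sub[sub[spec.response] > 0]
    n_dropped = len(df) - len(sub)

    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    std = {}
    for c in spec.covariates:
        v = sub[c].to_numpy(dtype=float)
        if spec.standardize:
            m, s = float(v.mean()), float(v.std(ddof=0))
            s = s if s > 0 else 1.0
        else:
            m, s = 0.0, 1.0
        std[c] = (m, s)
        X[c] = (v - m) / s
    t = (sub["forest_type"] == "planted").astype(float).to_numpy()
    if spec.include_type:
        X["type"] = t
    for c in spec.interactions:
        X[f"type:{c}"] = t * X[c].to_numpy()
    y = np.log(sub[spec.response].to_numpy(dtype=float))
    groups = sub[spec.grouping].to_numpy()
    return y, X, groups, std, n_dropped


def fit_mixed(ds: Dataset, spec: MixedModelSpec, reml: bool = True) -> MixedModelFit:
    """Fit one mixed model; REML by default (use ML for AIC comparisons)."""
    spec = spec.validate()
    y, X, groups, std, n_dropped = _design(ds, spec)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 studies for a random intercept")
    spec = replace(spec, standardization=std)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method="powell")
        if not res.converged:
            res = model.fit(reml=reml, method="powell")

    k = X.shape[1]
    params = res.params.iloc[:k]
    se = res.bse.iloc[:k]
    pvals = res.pvalues.iloc[:k]
    coef = pd.DataFrame({
        "estimate": params, "se": se,
        "ci_low": params - 1.96 * se, "ci_high": params + 1.96 * se,
        "p": pvals,
    })

    # per-raw-unit versions: divide standardized terms by the sd used
    scale = pd.Series(1.0, index=coef.index)
    for c in spec.covariates:
        scale[c] = std[c][1]
        if f"type:{c}" in scale.index:
            scale[f"type:{c}"] = std[c][1]
    raw = coef.copy()
    for col in ("estimate", "se", "ci_low", "ci_high"):
        raw[col] = coef[col] / scale

    var_study = float(np.asarray(res.cov_re).ravel()[0])
    var_resid = float(res.scale)
    fixed_pred = X.to_numpy() @ params.to_numpy()
    var_f = float(np.var(fixed_pred))
    denom = var_f + var_study + var_resid
    llf = float(res.llf)
    aic = -2.0 * llf + 2.0 * (k + 2)  # +2: random-intercept and residual variances

    return MixedModelFit(
        spec=spec, coefficients=coef, coefficients_raw=raw,
        cov_params=res.cov_params().iloc[:k, :k],
        var_study=var_study, var_resid=var_resid, loglike=llf, aic=aic,
        r2_marginal=var_f / denom, r2_conditional=(var_f + var_study) / denom,
        n_used=len(y), n_dropped=n_dropped,
        converged=bool(res.converged), reml=reml,
    )


def _droppable_terms(spec: MixedModelSpec) -> list[str]:
    """Terms removable without violating marginality.

    Interactions are always droppable; a covariate main effect only once its
    interaction is gone; the type main effect only once all interactions are
    gone. The intercept is never dropped.
    """
    out = [f"type:{c}" for c in spec.interactions]
    out += [c for c in spec.covariates if c not in spec.interactions]
    if spec.include_type and not spec.interactions:
        out.append("type")
    return out


def _drop_term(spec: MixedModelSpec, term: str) -> MixedModelSpec:
    if term.startswith("type:"):
        c = term.split(":", 1)[1]
        return replace(spec, interactions=[x for x in spec.interactions if x != c])
    if term == "type":
        return replace(spec, include_type=False)
    return replace(spec, covariates=[x for x in spec.covariates if x != term])


def backward_eliminate(ds: Dataset, full_spec: MixedModelSpec,
                       tie_tolerance: float = 0.01
                       ) -> tuple[MixedModelSpec, list[dict]]:
    """AIC backward elimination under ML, honouring marginality.

    At each step the candidate whose removal lowers AIC most is dropped;
    removals within ``tie_tolerance`` of the current AIC count as ties and
    the smaller model is preferred. Returns the selected spec and the
    elimination path (one entry per step with the AICs considered).
    """
    spec = full_spec.validate()
    current = fit_mixed(ds, spec, reml=False)
    path: list[dict] = []
    while True:
        candidates = _droppable_terms(spec)
        if not candidates:
            break
        trials = {}
        for term in candidates:
            trial_spec = _drop_term(spec, term)
            trials[term] = fit_mixed(ds, trial_spec, reml=False).aic
        best_term = min(trials, key=trials.get)
        step = {"aic_current": current.aic, "candidates": trials,
                "dropped": None}
        if trials[best_term] - current.aic < tie_tolerance:
            spec = _drop_term(spec, best_term)
            current = fit_mixed(ds, spec, reml=False)
            step["dropped"] = best_term
            path.append(step)
        else:
            path.append(step)
            break
    return spec, path


def marginal_effect(fit: MixedModelFit, covariate: str = "mat",
                    grid: np.ndarray | None = None) -> pd.DataFrame:
    """Predicted ln-response curve vs one covariate, by forest type.

    Other covariates are held at their standardized mean (0). ``grid`` is in
    standardized units (default: 41 points over +/-2 SD). Returns both the
    ln-scale curve with a 95% Wald band and the back-transformed scale.
    """
    if covariate not in fit.spec.covariates:
        raise ValueError(f"{covariate!r} is not in the fitted model")
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 41)
    grid = np.asarray(grid, dtype=float)
    terms = list(fit.coefficients.index)
    V = fit.cov_params.to_numpy()
    beta = fit.coefficients["estimate"].to_numpy()

    rows = []
    for ftype, t in (("natural", 0.0), ("planted", 1.0)):
        for x in grid:
            c = np.zeros(len(terms))
            c[terms.index("intercept")] = 1.0
            c[terms.index(covariate)] = x
            if "type" in terms:
                c[terms.index("type")] = t
            iname = f"type:{covariate}"
            if iname in terms:
                c[terms.index(iname)] = t * x
            mu = float(c @ beta)
            sd = float(np.sqrt(c @ V @ c))
            rows.append({"forest_type": ftype, "z": x, "ln_mean": mu,
                         "ln_low": mu - 1.96 * sd, "ln_high": mu + 1.96 * sd,
                         "mean": np.exp(mu), "low": np.exp(mu - 1.96 * sd),
                         "high": np.exp(mu + 1.96 * sd)})
    return pd.DataFrame(rows)


def predict_ln(fit: MixedModelFit, df: pd.DataFrame) -> np.ndarray:
    """Fixed-effect ln-scale prediction for new rows (study effect at 0)."""
    spec = fit.spec
    work = df.copy()
    if "mineral" in spec.covariates and "mineral" not in work.columns:
        work["mineral"] = _encode_mineral(work["mineral_class"])
    X = pd.DataFrame(index=work.index)
    X["intercept"] = 1.0
    for c in spec.covariates:
        m, s = spec.standardization[c]
        X[c] = (work[c].to_numpy(dtype=float) - m) / s
    t = (work["forest_type"] == "planted").astype(float).to_numpy()
    if spec.include_type:
        X["type"] = t
    for c in spec.interactions:
        X[f"type:{c}"] = t * X[c].to_numpy()
    return X[list(fit.coefficients.index)].to_numpy() @ \
        fit.coefficients["estimate"].to_numpy()
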