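"""Synthetic observation tables, covariate grids and meta-analysis tables.

The generative model mirrors the structure used throughout the package: the
natural log of a soil carbon fraction (MAOC or POC, g C kg^-1) is linear in
standardized environmental covariates, with a forest-type main effect
(plantations lower), forest-type x climate interactions (warming and drying
hit plantations harder), a study-level random intercept, and lognormal
residual noise:

    ln y = b0 + sum_j b_j z_j + T (b_T + b_Tm z_mat + b_Ta z_ai)
           + u_study + eps,   u ~ N(0, s_study^2),  eps ~ N(0, s_resid^2)

with T = 1 for planted, 0 for natural. Covariates are drawn uniformly over
field-realistic ranges (MAT -5..21 degC etc.) and standardized with the
theoretical moments of those ranges, so true coefficients are directly
comparable to fitted standardized coefficients.

Every generator returns the exact ground truth needed by recovery tests:
coefficients, per-cell counterfactual mean ln-concentrations, conditional
quantiles, and total stock / deficit in Pg C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.stats import norm

from .core_data import (CovariateGrid, Dataset, FOREST_CODES, REGION_CODES,
                        validate_observations)

#: (low, high) sampling ranges for each continuous covariate
COVARIATE_RANGES = {
    "mat": (-5.0, 21.0),          # degC
    "ai": (0.2, 2.0),             # precip / PET
    "npp": (100.0, 1200.0),       # g C m^-2 yr^-1
    "elevation": (0.0, 4000.0),   # m
    "ph": (4.0, 8.5),
    "clay_silt": (30.0, 95.0),    # %
}

P_HIGH_ACTIVITY = 0.8   # share of high-activity mineral soils
DEPTH_BOTTOM_CHOICES = (10.0, 20.0)  # cm; upper is always 0


def _uniform_moments(lo: float, hi: float) -> tuple[float, float]:
    return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


#: standardization constants shared by generation and ground-truth math
STANDARDIZATION = {k: _uniform_moments(*v) for k, v in COVARIATE_RANGES.items()}
# depth takes two equiprobable values; exact two-point moments
STANDARDIZATION["depth_bottom"] = (float(np.mean(DEPTH_BOTTOM_CHOICES)),
                                   float(np.std(DEPTH_BOTTOM_CHOICES)))
STANDARDIZATION["mineral"] = (P_HIGH_ACTIVITY,
                              np.sqrt(P_HIGH_ACTIVITY * (1 - P_HIGH_ACTIVITY)))


def standardize(name: str, values):
    mean, sd = STANDARDIZATION[name]
    return (np.asarray(values, dtype=float) - mean) / sd


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic generative model.

    All coefficients act on the ln-concentration scale over standardized
    covariates. ``delta_ln`` is the ln-scale natural-minus-planted offset at
    average climate used for deficit ground truth; if given it overrides
    ``beta_type`` (they satisfy ``delta_ln = -beta_type``).
    """

    seed: int = 0
    response: str = "maoc"
    n_studies: int = 71
    sites_per_study: int = 15
    beta0: float = 2.5
    beta_type: float = -0.92
    beta_mat: float = -0.35
    beta_ai: float = 0.20
    beta_type_mat: float = -0.15
    beta_type_ai: float = 0.10
    beta_npp: float = 0.10
    beta_elevation: float = 0.05
    beta_ph: float = -0.10
    beta_clay_silt: float = 0.15
    beta_depth: float = -0.08
    beta_mineral: float = 0.08
    sigma_study: float = 0.15
    sigma_resid: float = 0.28
    p_planted: float = 0.47
    grid_shape: tuple[int, int] = (30, 30)
    spatial_smoothness: float = 3.0
    cell_area: float = 4.0e9           # m^2 per cell
    frac_nonforest: float = 0.20
    frac_planted: float = 0.40         # of all cells; remainder is natural
    delta_ln: Optional[float] = None
    depth_cm: float = 20.0             # depth the grid truth refers to

    def __post_init__(self):
        if self.delta_ln is not None:
            self.beta_type = -float(self.delta_ln)
        else:
            self.delta_ln = -float(self.beta_type)
        if self.sigma_study < 0 or self.sigma_resid < 0:
            raise ValueError("standard deviations must be >= 0")
        if min(self.grid_shape) < 4:
            raise ValueError("grid_shape must be at least 4x4")

    @property
    def n_sites(self) -> int:
        return self.n_studies * self.sites_per_study

    def main_effects(self) -> dict[str, float]:
        return {
            "mat": self.beta_mat, "ai": self.beta_ai, "npp": self.beta_npp,
            "elevation": self.beta_elevation, "ph": self.beta_ph,
            "clay_silt": self.beta_clay_silt, "depth_bottom": self.beta_depth,
            "mineral": self.beta_mineral,
        }


@dataclass
class GroundTruth:
    """Exact quantities implied by a :class:`GeneratorConfig`."""

    coefficients: dict
    sigma_study: float
    sigma_resid: float
    #: grid-only fields (None for pure observation draws)
    mu_natural: Optional[np.ndarray] = None
    mu_planted: Optional[np.ndarray] = None
    quantiles_natural: dict = field(default_factory=dict)
    total_stock_pg: Optional[float] = None
    deficit_pg: Optional[float] = None


def _linear_predictor(cfg: GeneratorConfig, z: dict[str, np.ndarray],
                      planted: np.ndarray) -> np.ndarray:
    mu = np.full(np.shape(planted), cfg.beta0, dtype=float)
    for name, beta in cfg.main_effects().items():
        mu += beta * z[name]
    t = np.asarray(planted, dtype=float)
    mu += t * (cfg.beta_type + cfg.beta_type_mat * z["mat"]
               + cfg.beta_type_ai * z["ai"])
    return mu


def _truth_coefficients(cfg: GeneratorConfig) -> dict:
    out = {"intercept": cfg.beta0, "type": cfg.beta_type,
           "type:mat": cfg.beta_type_mat, "type:ai": cfg.beta_type_ai}
    out.update(cfg.main_effects())
    return out


def generate_observations(cfg: GeneratorConfig,
                          companion: GeneratorConfig | None = None
                          ) -> tuple[Dataset, GroundTruth]:
    """Draw a synthetic observation table plus its ground truth.

    ``companion`` optionally supplies the generative model for the *other*
    carbon fraction (e.g. POC when ``cfg.response`` is MAOC); both responses
    then share sites, covariates and study structure but have independent
    noise. Without it the other fraction's column is left missing.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    study = np.repeat(np.arange(cfg.n_studies), cfg.sites_per_study)

    cov = {k: rng.uniform(lo, hi, size=n) for k, (lo, hi) in COVARIATE_RANGES.items()}
    mineral = (rng.random(n) < P_HIGH_ACTIVITY).astype(int)
    depth_bottom = rng.choice(DEPTH_BOTTOM_CHOICES, size=n)
    planted = (rng.random(n) < cfg.p_planted).astype(int)
    lon = rng.uniform(81.0, 132.0, size=n)
    lat = rng.uniform(21.0, 53.0, size=n)

    z = {k: standardize(k, v) for k, v in cov.items()}
    z["mineral"] = standardize("mineral", mineral)
    z["depth_bottom"] = standardize("depth_bottom", depth_bottom)

    def draw_response(c: GeneratorConfig, noise_rng) -> np.ndarray:
        mu = _linear_predictor(c, z, planted)
        u = noise_rng.normal(0.0, c.sigma_study, size=c.n_studies)[study]
        eps = noise_rng.normal(0.0, c.sigma_resid, size=n)
        return np.exp(mu + u + eps)

    primary = draw_response(cfg, rng)
    other = None
    if companion is not None:
        other = draw_response(companion, rng)

    region = np.where(lat >= 37.0, np.where(lon >= 110.0, "NE", "NO"),
                      np.where(lon >= 110.0, "SE", "SW"))
    df = pd.DataFrame({
        "site_id": [f"s{i:05d}" for i in range(n)],
        "study_id": [f"study{g:03d}" for g in study],
        "forest_type": np.where(planted == 1, "planted", "natural"),
        "region": region,
        "lon": lon, "lat": lat,
        "depth_upper": 0.0, "depth_bottom": depth_bottom,
        "mat": cov["mat"], "ai": cov["ai"], "npp": cov["npp"],
        "elevation": cov["elevation"], "ph": cov["ph"],
        "clay_silt": cov["clay_silt"],
        "mineral_class": np.where(mineral == 1, "high_activity", "low_activity"),
        "maoc": np.nan, "poc": np.nan,
    })
    df[cfg.response] = primary
    if other is not None:
        df[companion.response] = other

    truth = GroundTruth(coefficients=_truth_coefficients(cfg),
                        sigma_study=cfg.sigma_study, sigma_resid=cfg.sigma_resid)
    ds = validate_observations(df, provenance=f"synthetic seed={cfg.seed}")
    assert not ds.rejected, "generator produced invalid rows"
    return ds, truth


def _smooth_uniform(rng, shape, smoothness, lo=0.0, hi=1.0):
    """Spatially smooth field with uniform(lo, hi) marginals.

    Gaussian-filtered white noise is re-standardized and mapped through the
    normal CDF, giving a smooth field whose values are uniform on (lo, hi).
    """
    f = rng.normal(size=shape)
    if smoothness > 0:
        f = gaussian_filter(f, sigma=smoothness, mode="wrap")
        sd = f.std()
        if sd > 0:
            f = f / sd
    return lo + (hi - lo) * norm.cdf(f)


def generate_grid(cfg: GeneratorConfig) -> tuple[CovariateGrid, GroundTruth]:
    """Draw a smooth synthetic covariate grid plus exact truth layers.

    Ground-truth concentrations are true expected concentrations (the
    lognormal mean ``exp(mu + sigma_tot^2/2)``); conditional quantiles add
    ``z_q * sqrt(sigma_study^2 + sigma_resid^2)`` to ``mu`` on the ln
    scale. Stocks and deficits are integrated over forest cells at
    ``cfg.depth_cm``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    shape = tuple(cfg.grid_shape)
    s = cfg.spatial_smoothness

    cov = {k: _smooth_uniform(rng, shape, s, lo, hi)
           for k, (lo, hi) in COVARIATE_RANGES.items()}
    mineral = (_smooth_uniform(rng, shape, s) < P_HIGH_ACTIVITY).astype(int)
    bd = _smooth_uniform(rng, shape, s, 0.9, 1.6)
    coarse = _smooth_uniform(rng, shape, s, 0.0, 0.30)

    u = _smooth_uniform(rng, shape, s)
    forest_mask = np.full(shape, FOREST_CODES["natural"], dtype=int)
    forest_mask[u < cfg.frac_nonforest] = FOREST_CODES["nonforest"]
    forest_mask[(u >= cfg.frac_nonforest)
                & (u < cfg.frac_nonforest + cfg.frac_planted)] = FOREST_CODES["planted"]

    rows, cols = np.indices(shape)
    north = rows < shape[0] // 2
    west = cols < shape[1] // 2
    region_mask = np.where(north, np.where(west, REGION_CODES["NO"], REGION_CODES["NE"]),
                           np.where(west, REGION_CODES["SW"], REGION_CODES["SE"]))

    grid = CovariateGrid(
        mat=cov["mat"], ai=cov["ai"], npp=cov["npp"], elevation=cov["elevation"],
        ph=cov["ph"], clay_silt=cov["clay_silt"], mineral=mineral,
        bd=bd, coarse_frac=coarse, forest_mask=forest_mask,
        region_mask=region_mask, cell_area=cfg.cell_area,
    ).validate()

    z = {k: standardize(k, cov[k]) for k in cov}
    z["mineral"] = standardize("mineral", mineral)
    z["depth_bottom"] = standardize("depth_bottom",
                                    np.full(shape, cfg.depth_cm))
    mu_nat = _linear_predictor(cfg, z, np.zeros(shape))
    mu_pl = _linear_predictor(cfg, z, np.ones(shape))

    sigma_tot = float(np.hypot(cfg.sigma_study, cfg.sigma_resid))
    quants = {q: mu_nat + norm.ppf(q) * sigma_tot for q in (0.6, 0.8, 0.9)}

    # stock integration on the expected-concentration scale: the true mean
    # of a lognormal site is exp(mu + sigma_tot^2 / 2)
    lognormal_mean = np.exp(0.5 * sigma_tot**2)
    per_kg = grid.bd * (1 - grid.coarse_frac) * cfg.depth_cm * 0.01  # kg m^-2 per g kg^-1
    planted_cells = forest_mask == FOREST_CODES["planted"]
    natural_cells = forest_mask == FOREST_CODES["natural"]
    conc_asis = np.where(planted_cells, np.exp(mu_pl), np.exp(mu_nat)) * lognormal_mean
    stock = np.where(planted_cells | natural_cells, conc_asis * per_kg, 0.0)
    total_pg = float(stock.sum() * cfg.cell_area * 1e-12)
    deficit = np.where(planted_cells,
                       (np.exp(mu_nat) - np.exp(mu_pl)) * lognormal_mean * per_kg,
                       0.0)
    deficit_pg = float(deficit.sum() * cfg.cell_area * 1e-12)

    truth = GroundTruth(
        coefficients=_truth_coefficients(cfg),
        sigma_study=cfg.sigma_study, sigma_resid=cfg.sigma_resid,
        mu_natural=mu_nat, mu_planted=mu_pl, quantiles_natural=quants,
        total_stock_pg=total_pg, deficit_pg=deficit_pg,
    )
    for lo_q, hi_q in ((0.6, 0.8), (0.8, 0.9)):
        assert (truth.quantiles_natural[lo_q] <= truth.quantiles_natural[hi_q]).all()
    return grid, truth


def uniform_mgf(a: float) -> float:
    """E[exp(a Z)] for Z uniform on (-sqrt(3), sqrt(3)) (standardized uniform)."""
    x = np.sqrt(3.0) * a
    return float(np.sinh(x) / x) if abs(x) > 1e-12 else 1.0


def expected_mean_ratio(cfg: GeneratorConfig) -> float:
    """Exact natural:planted ratio of expected concentrations.

    Study and residual lognormal factors are type-independent and cancel;
    what remains is the type offset and the interaction-induced shift in the
    climate-term moment generating functions.
    """
    num = uniform_mgf(cfg.beta_mat) * uniform_mgf(cfg.beta_ai)
    den = (uniform_mgf(cfg.beta_mat + cfg.beta_type_mat)
           * uniform_mgf(cfg.beta_ai + cfg.beta_type_ai))
    return float(np.exp(-cfg.beta_type) * num / den)


def calibrate_type_effect(cfg: GeneratorConfig, target_ratio: float) -> float:
    """Return the ``beta_type`` giving an exact population mean ratio."""

    def f(bt):
        c = GeneratorConfig(**{**cfg.__dict__, "beta_type": bt, "delta_ln": None})
        return expected_mean_ratio(c) - target_ratio

    return float(brentq(f, -5.0, 0.5))


def default_config(response: str = "maoc", seed: int = 0) -> GeneratorConfig:
    """Calibrated defaults emulating the national MAOC/POC compilation.

    Sample size (71 studies x 15 sites = 1065 cases), covariate ranges,
    effect signs, natural:planted mean ratios (2.3 for MAOC, 2.5 for POC)
    and signal-to-noise are set to the conditions of the study system; see
    docs/methods.md for the calibration.
    """
    if response == "maoc":
        cfg = GeneratorConfig(seed=seed, response="maoc")
        cfg.beta_type = calibrate_type_effect(cfg, 2.3)
        cfg.delta_ln = -cfg.beta_type
        return cfg
    if response == "poc":
        cfg = GeneratorConfig(
            seed=seed, response="poc", beta0=2.2, beta_mat=-0.30, beta_ai=0.05,
            beta_type_mat=-0.12, beta_type_ai=0.12, beta_npp=0.12,
            beta_elevation=0.03, beta_ph=-0.08, beta_clay_silt=0.10,
            beta_depth=-0.10, beta_mineral=0.05, sigma_resid=0.30,
        )
        cfg.beta_type = calibrate_type_effect(cfg, 2.5)
        cfg.delta_ln = -cfg.beta_type
        return cfg
    raise ValueError(f"unknown response {response!r}")


def generate_meta_table(seed: int, n_studies: int, true_rr: float,
                        tau2: float, duration_effect: float = 0.0,
                        mean_duration: float = 15.0,
                        n_reps: int = 5, control_mean: float = 20.0,
                        cv: float = 0.2) -> tuple[pd.DataFrame, dict]:
    """Synthetic close-to-nature meta-analysis table.

    Each study's true ln response ratio is
    ``true_rr + duration_effect * (duration - mean_duration) + N(0, tau2)``;
    observed treatment/control means then carry within-study sampling error
    from ``n_reps`` replicates with coefficient of variation ``cv``.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    rng = np.random.default_rng(seed)
    duration = rng.uniform(5.0, 25.0, size=n_studies)
    theta = (true_rr + duration_effect * (duration - mean_duration)
             + rng.normal(0.0, np.sqrt(tau2), size=n_studies))

    mc = np.full(n_studies, control_mean)
    mt = mc * np.exp(theta)
    sc, st = cv * mc, cv * mt
    xc = rng.normal(mc, sc / np.sqrt(n_reps))
    xt = rng.normal(mt, st / np.sqrt(n_reps))
    xc = np.maximum(xc, 1e-6)
    xt = np.maximum(xt, 1e-6)

    df = pd.DataFrame({
        "study_id": [f"m{i:03d}" for i in range(n_studies)],
        "xt": xt, "xc": xc, "st": st, "sc": sc,
        "nt": n_reps, "nc": n_reps,
        "duration": duration, "depth": 20.0,
    })
    truth = {"true_rr": true_rr, "tau2": tau2,
             "duration_effect": duration_effect,
             "percent_change": (np.exp(true_rr) - 1) * 100.0}
    return df, truth
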