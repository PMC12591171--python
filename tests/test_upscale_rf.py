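"""Learner comparison, forest upscaler, bootstrap maps and quantile forest."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from socbench import synthetic_data as sd
from socbench import upscale_rf as ur


def _dataset(seed=0, n_studies=20, sites=20, **cfg_overrides):
    cfg = sd.default_config("maoc", seed=seed)
    cfg.n_studies, cfg.sites_per_study = n_studies, sites
    for k, v in cfg_overrides.items():
        setattr(cfg, k, v)
    ds, truth = sd.generate_observations(cfg)
    return ds, truth, cfg


class TestCompareLearners:
    def test_folds_partition_and_determinism(self, obs_small):
        ds, _, _ = obs_small
        learners = {"linear_regression": ur.default_learners()["linear_regression"],
                    "regression_tree": ur.default_learners()["regression_tree"]}
        a = ur.compare_learners(ds, "maoc", learners=learners, seed=3)
        b = ur.compare_learners(ds, "maoc", learners=learners, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.winner == b.winner

    def test_linear_truth_favours_linear_model(self):
        # no interactions: ln response is exactly additive in the predictors
        ds, _, _ = _dataset(seed=8, beta_type_mat=0.0, beta_type_ai=0.0,
                            sigma_resid=0.25)
        learners = {k: v for k, v in ur.default_learners(n_trees=150).items()
                    if k in ("linear_regression", "random_forest")}
        rep = ur.compare_learners(ds, "maoc", learners=learners, seed=0)
        t = rep.table.set_index("learner")
        assert t.loc["linear_regression", "rmse"] <= t.loc["random_forest", "rmse"]

    def test_interaction_truth_favours_forest(self):
        ds, _, _ = _dataset(seed=9, beta_type_mat=-0.8, beta_type_ai=0.6,
                            sigma_resid=0.10)
        learners = {k: v for k, v in ur.default_learners(n_trees=150).items()
                    if k in ("linear_regression", "random_forest")}
        rep = ur.compare_learners(ds, "maoc", learners=learners, seed=0)
        assert rep.winner == "random_forest"

    def test_degenerate_response_rejected(self, obs_small):
        from socbench.core_data import Dataset
        ds, _, _ = obs_small
        flat = Dataset(records=ds.records.assign(maoc=5.0))
        with pytest.raises(ValueError, match="zero variance"):
            ur.compare_learners(ds=flat, response="maoc")


class TestFitUpscaler:
    def test_importances_normalized_and_mat_dominant(self, obs_small):
        ds, _, _ = obs_small
        fit = ur.fit_upscaler(ds, "maoc", n_trees=200, seed=0)
        imp = fit.importances
        assert (imp >= 0).all()
        assert imp.sum() == pytest.approx(1.0)
        # climate and forest type carry the signal in the generative model
        assert imp.sort_values(ascending=False).index[0] in ("mat", "type")

    def test_null_predictor_importance_small(self):
        ds, _, _ = _dataset(seed=13, n_studies=100, sites=20,
                            beta_ph=0.0, sigma_resid=0.15)
        fit = ur.fit_upscaler(ds, "maoc", n_trees=300, seed=0)
        assert fit.importances["ph"] < 0.05

    def test_tree_count_insensitivity(self, obs_small):
        ds, _, _ = obs_small
        r250 = ur.fit_upscaler(ds, "maoc", n_trees=250, seed=0).oob_r2
        r1000 = ur.fit_upscaler(ds, "maoc", n_trees=1000, seed=0).oob_r2
        assert abs(r250 - r1000) < 0.02

    def test_importance_invariant_to_record_order(self, obs_small):
        from socbench.core_data import Dataset
        ds, _, _ = obs_small
        rng = np.random.default_rng(1)
        shuffled = Dataset(records=ds.records.sample(
            frac=1.0, random_state=5).reset_index(drop=True))
        a = ur.fit_upscaler(ds, "maoc", n_trees=150, seed=0).importances
        b = ur.fit_upscaler(shuffled, "maoc", n_trees=150, seed=0).importances
        # same data, same seed: rankings agree on the dominant predictors
        assert list(a.sort_values(ascending=False).index[:2]) \
            == list(b.sort_values(ascending=False).index[:2])


class TestResiduals:
    def test_oob_residuals_centred_and_deterministic(self, obs_small):
        ds, _, _ = obs_small
        fit = ur.fit_upscaler(ds, "maoc", n_trees=300, seed=0)
        rt = ur.residual_table(fit, ds)
        assert abs(rt["residual"].mean()) < 0.05
        rt2 = ur.residual_table(ur.fit_upscaler(ds, "maoc", n_trees=300,
                                                seed=0), ds)
        np.testing.assert_allclose(rt["residual"], rt2["residual"])

    def test_cv_r2_tracks_noise_level(self):
        r2s = []
        for sigma in (0.15, 0.60):
            vals = []
            for seed in (31, 32):
                ds, _, _ = _dataset(seed=seed, n_studies=30, sites=20,
                                    sigma_resid=sigma)
                vals.append(ur.cv_metrics(ds, "maoc", folds=5, seed=0,
                                          n_trees=100)["r2"])
            r2s.append(np.mean(vals))
        assert r2s[0] > r2s[1] + 0.1

    def test_cv_r2_approaches_noise_ceiling(self):
        cfg = sd.default_config("maoc", seed=50)
        cfg.n_studies, cfg.sites_per_study = 250, 20   # n = 5000
        ds, _ = sd.generate_observations(cfg)
        X, y = ur.design_matrix(ds, "maoc")
        noise = cfg.sigma_resid**2 + cfg.sigma_study**2
        ceiling = 1.0 - noise / np.var(y)
        r2 = ur.cv_metrics(ds, "maoc", folds=10, seed=0, n_trees=150)["r2"]
        assert abs(r2 - ceiling) < 0.05


class TestBootstrapMaps:
    def test_noise_free_replicate_spread_collapses(self, landscape_small):
        grid, _, _ = landscape_small
        ds0, _, _ = _dataset(seed=17, n_studies=100, sites=20,
                             sigma_resid=0.0, sigma_study=0.0)
        noise_free = ur.bootstrap_predict(ds0, grid, "maoc", B=10, seed=0,
                                          n_trees=50)
        ds1, _, _ = _dataset(seed=17, n_studies=100, sites=20)
        noisy = ur.bootstrap_predict(ds1, grid, "maoc", B=10, seed=0,
                                     n_trees=50)
        rel0 = np.nanmean((noise_free.q95 - noise_free.q05) / noise_free.mean)
        rel1 = np.nanmean((noisy.q95 - noisy.q05) / noisy.mean)
        # remaining spread is subsample approximation variability only
        assert rel0 < 0.20
        assert rel0 < rel1

    def test_nonforest_cells_are_nan(self, obs_small, landscape_small):
        ds, _, _ = obs_small
        grid, _, _ = landscape_small
        maps = ur.bootstrap_predict(ds, grid, "maoc", B=4, seed=0, n_trees=25)
        off = grid.forest_mask == 0
        assert np.isnan(maps.mean[off]).all()
        assert not np.isnan(maps.mean[~off]).any()

    def test_band_contains_mean(self, obs_small, landscape_small):
        ds, _, _ = obs_small
        grid, _, _ = landscape_small
        maps = ur.bootstrap_predict(ds, grid, "maoc", B=8, seed=1, n_trees=25)
        ok = ~np.isnan(maps.mean)
        assert (maps.q05[ok] <= maps.mean[ok]).all()
        assert (maps.mean[ok] <= maps.q95[ok]).all()

    def test_full_fraction_spread_smaller_than_subsample(self, obs_small,
                                                         landscape_small):
        ds, _, _ = obs_small
        grid, _, _ = landscape_small
        sub = ur.bootstrap_predict(ds, grid, "maoc", B=8, seed=2, n_trees=25,
                                   frac=0.70, calibrate=False)
        full = ur.bootstrap_predict(ds, grid, "maoc", B=8, seed=2, n_trees=25,
                                    frac=1.0, calibrate=False)
        assert np.nanmean(full.q95 - full.q05) < np.nanmean(sub.q95 - sub.q05)

    def test_replicate_mean_close_to_full_fit(self, landscape_small):
        grid, _, _ = landscape_small
        ds, _, _ = _dataset(seed=19, n_studies=60, sites=20)
        maps = ur.bootstrap_predict(ds, grid, "maoc", B=20, seed=0, n_trees=50,
                                    calibrate=False)
        fit = ur.fit_upscaler(ds, "maoc", n_trees=200, seed=0)
        single = ur.predict_concentration(fit, grid)
        ok = ~np.isnan(single)
        assert abs(np.mean(maps.mean[ok]) / np.mean(single[ok]) - 1) < 0.10

    def test_too_few_replicates_rejected(self, obs_small, landscape_small):
        ds, _, _ = obs_small
        grid, _, _ = landscape_small
        with pytest.raises(ValueError, match="B >= 2"):
            list(ur.bootstrap_models(ds, "maoc", B=1))


class TestQuantileForest:
    def test_lognormal_quantile_spread_oracle(self):
        # with no covariate signal the conditional distribution is pure
        # lognormal noise: q90 - q50 on the ln scale = 1.2816 * sigma
        cfg = sd.GeneratorConfig(seed=23, n_studies=100, sites_per_study=20,
                                 beta_mat=0, beta_ai=0, beta_npp=0,
                                 beta_elevation=0, beta_ph=0, beta_clay_silt=0,
                                 beta_depth=0, beta_mineral=0, beta_type=0,
                                 beta_type_mat=0, beta_type_ai=0,
                                 sigma_study=0.0, sigma_resid=0.40)
        ds, _ = sd.generate_observations(cfg)
        qf = ur.fit_quantile_forest(ds, "maoc", n_trees=150, seed=0)
        X, _ = ur.design_matrix(ds, "maoc")
        q = qf.predict_quantiles(X.to_numpy()[:50], [0.5, 0.9])
        spread = np.mean(q[:, 1] - q[:, 0])
        expected = norm.ppf(0.9) * cfg.sigma_resid
        assert abs(spread / expected - 1) < 0.15

    def test_quantiles_monotone_in_q(self, obs_small):
        ds, _, _ = obs_small
        qf = ur.fit_quantile_forest(ds, "maoc", n_trees=80, seed=0)
        X, _ = ur.design_matrix(ds, "maoc")
        q = qf.predict_quantiles(X.to_numpy()[:100], [0.6, 0.8, 0.9])
        assert (np.diff(q, axis=1) >= 0).all()

    def test_out_of_range_quantile_rejected(self, obs_small):
        ds, _, _ = obs_small
        qf = ur.fit_quantile_forest(ds, "maoc", n_trees=20, seed=0)
        X, _ = ur.design_matrix(ds, "maoc")
        with pytest.raises(ValueError):
            qf.predict_quantiles(X.to_numpy()[:2], [1.2])
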