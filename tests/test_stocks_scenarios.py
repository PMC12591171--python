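"""Stock integration, deficit estimation and quantile scenarios."""

import numpy as np
import pytest

from socbench import stocks_scenarios as ss
from socbench import synthetic_data as sd
from socbench import upscale_rf as ur
from socbench.core_data import CovariateGrid, FOREST_CODES


def _uniform_grid(value=1.0, shape=(4, 4), cell_area=1.0e9, bd=1.3,
                  coarse=0.0, forest_code=2):
    ones = np.ones(shape)
    return CovariateGrid(
        mat=ones * 10, ai=ones, npp=ones * 500, elevation=ones * 100,
        ph=ones * 6, clay_silt=ones * 60, mineral=np.ones(shape, dtype=int),
        bd=ones * bd, coarse_frac=ones * coarse,
        forest_mask=np.full(shape, forest_code, dtype=int),
        region_mask=np.tile([[1, 2], [3, 4]],
                            (shape[0] // 2, shape[1] // 2)),
        cell_area=cell_area,
    ).validate()


class TestStockEquation:
    def test_unit_arithmetic(self):
        # 20 g/kg x 1.3 g/cm3 x (1-0) x 20 cm x 0.01 = 5.2 kg C m^-2
        grid = _uniform_grid(bd=1.3, coarse=0.0)
        stock = ss.concentration_to_stock(np.full(grid.shape, 20.0), grid,
                                          depth_cm=20.0)
        np.testing.assert_allclose(stock, 5.2, rtol=1e-12)

    def test_full_coarse_fraction_annihilates(self):
        grid = _uniform_grid(coarse=1.0)
        stock = ss.concentration_to_stock(np.full(grid.shape, 20.0), grid)
        np.testing.assert_array_equal(stock, 0.0)

    def test_depth_linearity(self):
        grid = _uniform_grid()
        conc = np.full(grid.shape, 12.0)
        a = ss.concentration_to_stock(conc, grid, depth_cm=10)
        b = ss.concentration_to_stock(conc, grid, depth_cm=20)
        np.testing.assert_allclose(b, 2 * a)

    def test_negative_concentration_rejected(self):
        grid = _uniform_grid()
        conc = np.full(grid.shape, 5.0)
        conc[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            ss.concentration_to_stock(conc, grid)


class TestAggregate:
    def test_unit_conversion_to_pg(self):
        # 1 kg C m^-2 over 16 cells x 1e9 m^2 = 1.6e10 kg = 0.016 Pg
        grid = _uniform_grid(cell_area=1.0e9)
        out = ss.aggregate(np.ones(grid.shape), grid)
        assert out["total"] == pytest.approx(0.016, rel=1e-12)

    def test_regions_partition_total(self, landscape_small):
        grid, _, _ = landscape_small
        layer = np.abs(np.random.default_rng(0).normal(size=grid.shape))
        out = ss.aggregate(layer, grid, by="region_mask")
        assert sum(v for k, v in out.items() if k != "total") \
            == pytest.approx(out["total"], rel=1e-12)

    def test_empty_region_zero(self):
        grid = _uniform_grid()
        grid.region_mask[:] = 1   # everything SE
        out = ss.aggregate(np.ones(grid.shape), grid, by="region_mask")
        assert out["SW"] == 0.0 and out["SE"] == out["total"]

    def test_retiling_invariance(self):
        grid = _uniform_grid(shape=(4, 4), cell_area=4.0e9)
        layer = np.arange(16, dtype=float).reshape(4, 4)
        fine = _uniform_grid(shape=(8, 8), cell_area=1.0e9)
        fine_layer = np.kron(layer, np.ones((2, 2)))
        assert ss.aggregate(layer, grid)["total"] == pytest.approx(
            ss.aggregate(fine_layer, fine)["total"], rel=1e-12)

    def test_soc_is_sum_of_fractions(self, landscape_small):
        grid, _, _ = landscape_small
        rng = np.random.default_rng(1)
        maoc = np.abs(rng.normal(10, 2, grid.shape))
        poc = np.abs(rng.normal(6, 2, grid.shape))
        sm = ss.concentration_to_stock(maoc, grid)
        sp = ss.concentration_to_stock(poc, grid)
        s_sum = ss.concentration_to_stock(maoc + poc, grid)
        assert ss.aggregate(sm, grid)["total"] + ss.aggregate(sp, grid)["total"] \
            == pytest.approx(ss.aggregate(s_sum, grid)["total"], rel=1e-12)


class TestDeficit:
    def test_null_type_effect_gives_null_deficit(self):
        cfg = sd.default_config("maoc", seed=31)
        cfg.n_studies, cfg.sites_per_study = 40, 20
        cfg.delta_ln = 0.0
        cfg.beta_type = 0.0
        cfg.beta_type_mat = cfg.beta_type_ai = 0.0
        ds, _ = sd.generate_observations(cfg)
        grid, truth = sd.generate_grid(cfg)
        assert truth.deficit_pg == pytest.approx(0.0)
        d = ss.estimate_deficit(ds, grid, "maoc", B=10, seed=0, n_trees=30)
        noise_floor = max(d.total_hi_pg - d.total_lo_pg, 1e-6)
        assert abs(d.total_pg) < 3 * noise_floor

    def test_deficit_recovery_moderate_landscape(self):
        cfg = sd.default_config("maoc", seed=32)
        cfg.n_studies, cfg.sites_per_study = 100, 20
        ds, _ = sd.generate_observations(cfg)
        grid, truth = sd.generate_grid(cfg)
        d = ss.estimate_deficit(ds, grid, "maoc", B=20, seed=0, n_trees=25)
        assert abs(d.total_pg / truth.deficit_pg - 1) < 0.25

    def test_relabeling_natural_cells_leaves_deficit_unchanged(self, obs_small):
        ds, _, _ = obs_small
        cfg = sd.default_config("maoc", seed=33)
        cfg.grid_shape = (12, 12)
        grid, _ = sd.generate_grid(cfg)
        d1 = ss.estimate_deficit(ds, grid, "maoc", B=6, seed=0, n_trees=20)
        relabeled = CovariateGrid(**{**grid.__dict__})
        relabeled.forest_mask = grid.forest_mask.copy()
        relabeled.forest_mask[grid.forest_mask == FOREST_CODES["natural"]] \
            = FOREST_CODES["nonforest"]
        d2 = ss.estimate_deficit(ds, relabeled, "maoc", B=6, seed=0, n_trees=20)
        assert d2.total_pg == pytest.approx(d1.total_pg, rel=1e-9)

    def test_no_plantations_warns_and_zero(self, obs_small):
        ds, _, _ = obs_small
        grid = _uniform_grid(forest_code=FOREST_CODES["natural"], shape=(4, 4))
        with pytest.warns(UserWarning, match="no plantation"):
            d = ss.estimate_deficit(ds, grid, "maoc", B=4, seed=0, n_trees=10)
        assert d.total_pg == 0.0


@pytest.fixture(scope="module")
def scenario(obs_small, landscape_small):
    ds, _, _ = obs_small
    grid, _, _ = landscape_small
    maps = ur.bootstrap_predict(ds, grid, "maoc", B=8, seed=0, n_trees=40)
    current = ss.stock_map_from_bootstrap(maps, grid, "maoc")
    sc = ss.quantile_potential(ds, grid, "maoc", seed=0, n_trees=120,
                               current_map=current.mean)
    return sc, current, grid


class TestScenarios:
    def test_cellwise_and_aggregate_monotonicity(self, scenario):
        sc, _, _ = scenario
        q60, q80, q90 = (sc.potential_maps[q] for q in (0.6, 0.8, 0.9))
        ok = ~np.isnan(q60)
        assert (q60[ok] <= q80[ok] + 1e-12).all()
        assert (q80[ok] <= q90[ok] + 1e-12).all()
        assert sc.potential_pg[0.6] <= sc.potential_pg[0.8] <= sc.potential_pg[0.9]

    def test_additional_is_potential_minus_current(self, scenario):
        sc, _, _ = scenario
        for q in sc.quantiles:
            assert sc.additional_pg[q] == pytest.approx(
                sc.potential_pg[q] - sc.current_pg, rel=1e-12)

    def test_regional_breakdown_partitions_potential(self, scenario):
        sc, _, grid = scenario
        for q in sc.quantiles:
            assert sum(sc.per_region_pg[q].values()) \
                == pytest.approx(sc.potential_pg[q], rel=1e-9)

    def test_invalid_quantile_rejected(self, obs_small, landscape_small):
        ds, _, _ = obs_small
        grid, _, _ = landscape_small
        with pytest.raises(ValueError, match="quantiles"):
            ss.quantile_potential(ds, grid, "maoc", quantiles=[0.5, 1.5],
                                  current_map=np.zeros(grid.shape))

    def test_median_matches_natural_prediction_when_noise_free(self):
        cfg = sd.default_config("maoc", seed=35)
        cfg.n_studies, cfg.sites_per_study = 50, 20
        cfg.sigma_resid = cfg.sigma_study = 0.0
        ds, _ = sd.generate_observations(cfg)
        cfg.grid_shape = (12, 12)
        grid, truth = sd.generate_grid(cfg)
        sc = ss.quantile_potential(ds, grid, "maoc", quantiles=[0.5], seed=0,
                                   n_trees=150, current_map=np.zeros(grid.shape))
        # noise-free: conditional median == mean == exp(mu_natural)
        true_conc = np.exp(truth.mu_natural)
        true_stock = ss.concentration_to_stock(
            np.where(grid.forest_cells(), true_conc, np.nan), grid)
        true_pg = ss.aggregate(true_stock, grid)["total"]
        assert abs(sc.potential_pg[0.5] / true_pg - 1) < 0.10


class TestStockMapFromBootstrap:
    def test_totals_and_bounds_ordered(self, obs_small, landscape_small):
        ds, _, _ = obs_small
        grid, _, _ = landscape_small
        maps = ur.bootstrap_predict(ds, grid, "maoc", B=8, seed=0, n_trees=30,
                                    keep_stack=True)
        smap = ss.stock_map_from_bootstrap(maps, grid, "maoc")
        assert smap.total_lo_pg <= smap.total_pg <= smap.total_hi_pg
        assert sum(smap.per_region_pg.values()) \
            == pytest.approx(smap.total_pg, rel=1e-9)
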