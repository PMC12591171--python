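"""Stock integration, counterfactual deficits and quantile storage scenarios.

A concentration layer (g C kg^-1) converts to an areal stock (kg C m^-2) as

    stock = concentration x bulk_density x (1 - coarse_frac) x depth x 0.01

(the 0.01 reconciles g kg^-1, g cm^-3 and cm into kg m^-2). Totals multiply
by the uniform cell area and convert to Pg C (1 Pg = 1e12 kg).

The plantation deficit re-predicts plantation cells under a natural-forest
counterfactual with the conditional-mean forest; storage-potential
scenarios instead use conditional quantiles (0.60 minimal / 0.80
intermediate / 0.90 ambitious) from a quantile forest with forest type
forced to natural. Quantiles are estimated on the ln scale and
back-transformed (a monotone transform commutes with quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import CovariateGrid, FOREST_CODES, REGION_CODES, Dataset
from .upscale_rf import (BootstrapMaps, bootstrap_models, fit_quantile_forest,
                         grid_features)

KG_TO_PG = 1e-12
OBJECTIVES = {0.6: "minimal", 0.8: "intermediate", 0.9: "ambitious"}
DEFAULT_DEPTH_CM = 20.0   # topsoil depth of all stock maps


def concentration_to_stock(conc: np.ndarray, grid: CovariateGrid,
                           depth_cm: float = DEFAULT_DEPTH_CM) -> np.ndarray:
    """Per-cell stock (kg C m^-2) from a concentration layer (g C kg^-1)."""
    if depth_cm <= 0:
        raise ValueError("depth must be positive")
    conc = np.asarray(conc, dtype=float)
    if np.nanmin(conc) < 0:
        raise ValueError("negative concentration cell (upstream bug)")
    return conc * grid.bd * (1.0 - grid.coarse_frac) * depth_cm * 0.01


def aggregate(layer: np.ndarray, grid: CovariateGrid,
              by: str | None = None) -> dict[str, float]:
    """Totals in Pg C; NaN cells (off-mask) contribute nothing.

    ``by`` is ``"region_mask"`` or ``"forest_mask"``; grouped totals are
    disjoint and sum to ``"total"`` exactly.
    """
    layer = np.asarray(layer, dtype=float)
    vals = np.where(np.isnan(layer), 0.0, layer) * grid.cell_area * KG_TO_PG
    out = {"total": float(vals.sum())}
    if by is None:
        return out
    if by == "region_mask":
        codes = REGION_CODES
    elif by == "forest_mask":
        codes = FOREST_CODES
    else:
        raise ValueError(f"unknown mask {by!r}")
    mask = grid.layer(by)
    if not np.isin(mask, list(codes.values())).all():
        raise ValueError(f"unknown code in {by}")
    for name, code in codes.items():
        if name in ("none", "nonforest"):
            continue
        out[name] = float(vals[mask == code].sum())
    return out


@dataclass
class StockMap:
    """Per-cell stock layers and their aggregate totals for one fraction."""

    fraction: str                 # maoc | poc | soc
    depth_cm: float
    mean: np.ndarray              # kg C m^-2
    q05: np.ndarray
    q95: np.ndarray
    total_pg: float
    total_lo_pg: float
    total_hi_pg: float
    per_region_pg: dict[str, float]


def stock_map_from_bootstrap(maps: BootstrapMaps, grid: CovariateGrid,
                             fraction: str,
                             depth_cm: float = DEFAULT_DEPTH_CM) -> StockMap:
    """Convert bootstrap concentration maps to stock layers and totals.

    Total bounds come from the distribution of replicate *totals* when the
    replicate stack is available (the uncertainty the mapping reports);
    otherwise from summing the per-cell quantile layers (conservative).
    """
    mean = concentration_to_stock(maps.mean, grid, depth_cm)
    q05 = concentration_to_stock(maps.q05, grid, depth_cm)
    q95 = concentration_to_stock(maps.q95, grid, depth_cm)
    total = aggregate(mean, grid)["total"]
    if maps.replicate_stack is not None:
        totals = []
        for b in range(maps.B):
            stock_b = concentration_to_stock(maps.replicate_stack[b], grid, depth_cm)
            totals.append(aggregate(stock_b, grid)["total"])
        lo, hi = np.percentile(totals, [5, 95])
    else:
        lo = aggregate(q05, grid)["total"]
        hi = aggregate(q95, grid)["total"]
    region = aggregate(mean, grid, by="region_mask")
    region.pop("total", None)
    return StockMap(fraction=fraction, depth_cm=depth_cm, mean=mean,
                    q05=q05, q95=q95, total_pg=total,
                    total_lo_pg=float(min(lo, total)),
                    total_hi_pg=float(max(hi, total)),
                    per_region_pg=region)


@dataclass
class DeficitResult:
    """Counterfactual natural-minus-planted stock gap on plantation cells."""

    mean_map: np.ndarray          # kg C m^-2; 0 on natural, NaN off-forest
    total_pg: float
    total_lo_pg: float
    total_hi_pg: float
    replicate_totals_pg: np.ndarray
    per_region_pg: dict[str, float]
    B: int


def estimate_deficit(ds: Dataset, grid: CovariateGrid, response: str,
                     B: int = 100, frac: float = 0.70, seed: int = 0,
                     n_trees: int = 100,
                     depth_cm: float = DEFAULT_DEPTH_CM) -> DeficitResult:
    """Bootstrap estimate of the plantation stock deficit in Pg C.

    For every replicate forest, plantation cells are predicted twice -- as
    planted (as mapped) and re-labelled natural -- and the stock difference
    is integrated. Natural cells contribute zero by construction. The
    5%/95% bounds are quantiles of the replicate totals.
    """
    feats_nat, cells = grid_features(grid, "natural")
    feats_asis, _ = grid_features(grid, "asis")
    flat_forest_mask = grid.forest_mask.ravel()[cells]
    plantation = flat_forest_mask == FOREST_CODES["planted"]
    no_plantation = not plantation.any()
    if no_plantation:
        import warnings
        warnings.warn("no plantation cells; deficit is zero")

    per_kg = (grid.bd * (1.0 - grid.coarse_frac) * depth_cm * 0.01).ravel()[cells]
    area_pg = grid.cell_area * KG_TO_PG

    totals = np.zeros(B)
    acc = np.zeros(int(cells.sum()))
    for b, (rf, scale) in enumerate(bootstrap_models(ds, response, B=B,
                                                     frac=frac, seed=seed,
                                                     n_trees=n_trees)):
        if no_plantation:
            break
        c_nat = scale["natural"] * np.exp(rf.predict(feats_nat[plantation]))
        c_pl = scale["planted"] * np.exp(rf.predict(feats_asis[plantation]))
        d = np.zeros_like(acc)
        d[plantation] = (c_nat - c_pl) * per_kg[plantation]
        acc += d
        totals[b] = d.sum() * area_pg

    mean_flat = acc / B
    mean_map = np.full(cells.shape, np.nan)
    mean_map[cells] = mean_flat
    mean_map = mean_map.reshape(grid.shape)
    lo, hi = np.percentile(totals, [5, 95])
    region = aggregate(mean_map, grid, by="region_mask")
    region.pop("total", None)
    return DeficitResult(mean_map=mean_map, total_pg=float(totals.mean()),
                         total_lo_pg=float(lo), total_hi_pg=float(hi),
                         replicate_totals_pg=totals,
                         per_region_pg=region, B=B)


@dataclass
class ScenarioResult:
    """Quantile-based storage potentials versus current stock."""

    fraction: str
    quantiles: list[float]
    current_pg: float
    potential_pg: dict[float, float]
    additional_pg: dict[float, float]
    per_region_pg: dict[float, dict[str, float]]
    potential_maps: dict[float, np.ndarray]       # kg C m^-2
    additional_maps: dict[float, np.ndarray]
    objectives: dict[float, str] = field(default_factory=lambda: dict(OBJECTIVES))


def quantile_potential(ds: Dataset, grid: CovariateGrid, response: str,
                       quantiles=(0.60, 0.80, 0.90), seed: int = 0,
                       n_trees: int = 200, current_map: np.ndarray | None = None,
                       depth_cm: float = DEFAULT_DEPTH_CM) -> ScenarioResult:
    """Conditional-quantile storage potential under a natural counterfactual.

    A quantile forest predicts the q-quantile of ln-concentration on every
    forest cell with forest type forced to natural; back-transformed and
    integrated per objective and region. ``current_map`` is the current
    *stock* layer (kg C m^-2, e.g. from the bootstrap mean map); additional
    storage is potential minus current.
    """
    qs = sorted(float(q) for q in quantiles)
    if any(not 0 < q < 1 for q in qs):
        raise ValueError("quantiles must lie in (0, 1)")
    qf = fit_quantile_forest(ds, response, n_trees=n_trees, seed=seed)
    feats_nat, cells = grid_features(grid, "natural")
    ln_q = qf.predict_quantiles(feats_nat, qs)          # (n_cells, len(qs))

    if current_map is None:
        raise ValueError("current_map (current stock layer) is required")
    current_pg = aggregate(current_map, grid)["total"]

    potential_maps, additional_maps = {}, {}
    potential_pg, additional_pg, per_region = {}, {}, {}
    for j, q in enumerate(qs):
        conc = np.full(cells.shape, np.nan)
        conc[cells] = np.exp(ln_q[:, j])
        conc = conc.reshape(grid.shape)
        stock = concentration_to_stock(conc, grid, depth_cm)
        potential_maps[q] = stock
        additional_maps[q] = stock - np.where(np.isnan(current_map), 0.0, current_map)
        potential_pg[q] = aggregate(stock, grid)["total"]
        additional_pg[q] = potential_pg[q] - current_pg
        reg = aggregate(stock, grid, by="region_mask")
        reg.pop("total", None)
        per_region[q] = reg

    for lo_q, hi_q in zip(qs[:-1], qs[1:]):
        bad = np.nansum(potential_maps[lo_q] > potential_maps[hi_q] + 1e-12)
        assert bad == 0, "cell-wise quantile monotonicity violated"
    return ScenarioResult(fraction=response, quantiles=qs,
                          current_pg=current_pg, potential_pg=potential_pg,
                          additional_pg=additional_pg,
                          per_region_pg=per_region,
                          potential_maps=potential_maps,
                          additional_maps=additional_maps)
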