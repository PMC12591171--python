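"""Domain types, tabular/gridded I/O and validation shared by all pipeline stages.

Unit conventions (package-wide):

* concentrations (MAOC, POC)      g C kg^-1 soil
* bulk density                    g cm^-3
* coarse fraction                 volumetric proportion, 0-1
* depth                           cm
* per-cell stocks                 kg C m^-2
* aggregated totals               Pg C
* coordinates                     decimal degrees (WGS-84-like)

Grids are abstract equal-area cells with an explicit ``cell_area`` (m^2), so
regional and national totals require no projection math.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

FOREST_TYPES = ("planted", "natural")
REGIONS = ("SE", "SW", "NO", "NE")
MINERAL_CLASSES = ("high_activity", "low_activity")

#: integer codes used in gridded masks (NetCDF stores numbers, not strings)
FOREST_CODES = {"nonforest": 0, "planted": 1, "natural": 2}
REGION_CODES = {"none": 0, "SE": 1, "SW": 2, "NO": 3, "NE": 4}

#: canonical observation-table columns
OBS_COLUMNS = [
    "site_id", "study_id", "forest_type", "region", "lon", "lat",
    "depth_upper", "depth_bottom", "mat", "ai", "npp", "elevation",
    "ph", "clay_silt", "mineral_class", "maoc", "poc",
]

NUMERIC_COLUMNS = [
    "lon", "lat", "depth_upper", "depth_bottom", "mat", "ai", "npp",
    "elevation", "ph", "clay_silt", "maoc", "poc",
]

#: covariate layers a grid must provide (same quantities as observation rows)
GRID_COVARIATES = ["mat", "ai", "npp", "elevation", "ph", "clay_silt", "mineral"]
GRID_SOIL_LAYERS = ["bd", "coarse_frac"]
GRID_MASKS = ["forest_mask", "region_mask"]


class SchemaError(ValueError):
    """A mandatory column is missing or cannot be parsed."""


class GridError(ValueError):
    """Grid layers are inconsistent (shape, range or mask codes)."""


class InsufficientDataError(ValueError):
    """Not enough records in a group/stratum for the requested statistic."""


@dataclass
class Dataset:
    """Validated observation table: one row per forest site/case.

    ``records`` uses the columns in :data:`OBS_COLUMNS`. ``rejected`` keeps
    row-indexed messages for every input row that violated an invariant, so
    callers can audit what was dropped.
    """

    records: pd.DataFrame
    provenance: str = ""
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_planted(self) -> int:
        return int((self.records["forest_type"] == "planted").sum())

    @property
    def n_natural(self) -> int:
        return int((self.records["forest_type"] == "natural").sum())

    def __len__(self) -> int:
        return len(self.records)


def _row_problems(row: pd.Series) -> list[str]:
    msgs = []
    if row["forest_type"] not in FOREST_TYPES:
        msgs.append(f"forest_type {row['forest_type']!r} not in {FOREST_TYPES}")
    if row["region"] not in REGIONS:
        msgs.append(f"region {row['region']!r} not in {REGIONS}")
    if row["mineral_class"] not in MINERAL_CLASSES:
        msgs.append(f"mineral_class {row['mineral_class']!r} not in {MINERAL_CLASSES}")
    if not row["depth_upper"] < row["depth_bottom"]:
        msgs.append(f"depth_upper {row['depth_upper']} !< depth_bottom {row['depth_bottom']}")
    if not row["ai"] > 0:
        msgs.append(f"ai {row['ai']} must be > 0")
    if not 0 <= row["clay_silt"] <= 100:
        msgs.append(f"clay_silt {row['clay_silt']} outside [0, 100]")
    for resp in ("maoc", "poc"):
        v = row[resp]
        if pd.notna(v) and v < 0:
            msgs.append(f"{resp} {v} must be >= 0")
    if pd.isna(row["maoc"]) and pd.isna(row["poc"]):
        msgs.append("both maoc and poc missing")
    return msgs


def validate_observations(df: pd.DataFrame, provenance: str = "") -> Dataset:
    """Coerce types, apply row invariants, and return a :class:`Dataset`.

    Rows violating any invariant are dropped and reported in
    ``Dataset.rejected`` as ``(original_row_index, message)`` pairs.
    Raises :class:`SchemaError` for missing columns or unparseable numbers.
    """
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df = df[OBS_COLUMNS].copy()
    for col in NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            idx = int(df.index[bad][0])
            raise SchemaError(f"non-numeric value {df.loc[idx, col]!r} in column "
                              f"{col!r} at row {idx}")
        df[col] = coerced
    for col in ("forest_type", "region", "mineral_class"):
        df[col] = df[col].astype(str).str.strip()

    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for pos, (idx, row) in enumerate(df.iterrows()):
        problems = _row_problems(row)
        if problems:
            keep[pos] = False
            rejected.append((int(idx), "; ".join(problems)))
    return Dataset(records=df[keep].reset_index(drop=True),
                   provenance=provenance, rejected=rejected)


def read_observations(path, schema: dict[str, str] | None = None,
                      provenance: str | None = None) -> Dataset:
    """Read a delimited observation table and validate it.

    ``schema`` optionally maps canonical column names to the file's column
    names, e.g. ``{"mat": "MAT_degC"}``.
    """
    raw = pd.read_csv(path)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    return validate_observations(raw, provenance=provenance or str(path))


def write_observations(ds: Dataset, path) -> None:
    ds.records.to_csv(path, index=False)


@dataclass
class CovariateGrid:
    """Co-registered equal-area raster stack.

    All layers are 2-D arrays of identical shape. ``mineral`` is 1 for
    high-activity and 0 for low-activity minerals. Masks use the integer
    codes in :data:`FOREST_CODES` / :data:`REGION_CODES`. ``cell_area`` is
    the area of one cell in m^2 (uniform across the grid).
    """

    mat: np.ndarray
    ai: np.ndarray
    npp: np.ndarray
    elevation: np.ndarray
    ph: np.ndarray
    clay_silt: np.ndarray
    mineral: np.ndarray
    bd: np.ndarray
    coarse_frac: np.ndarray
    forest_mask: np.ndarray
    region_mask: np.ndarray
    cell_area: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mat.shape

    def layer(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def forest_cells(self) -> np.ndarray:
        """Boolean mask of planted or natural cells."""
        return self.forest_mask != FOREST_CODES["nonforest"]

    def validate(self) -> "CovariateGrid":
        names = GRID_COVARIATES + GRID_SOIL_LAYERS + GRID_MASKS
        shapes = {n: self.layer(n).shape for n in names}
        if len(set(shapes.values())) != 1:
            raise GridError(f"layers not co-registered: {shapes}")
        bad = np.argwhere((self.coarse_frac < 0) | (self.coarse_frac > 1))
        if bad.size:
            cell = tuple(int(i) for i in bad[0])
            raise GridError(f"coarse_frac outside [0, 1] at cell {cell}")
        forest = self.forest_cells()
        bad = np.argwhere(forest & ~(self.bd > 0))
        if bad.size:
            cell = tuple(int(i) for i in bad[0])
            raise GridError(f"bd <= 0 on forest cell {cell}")
        if not np.isin(self.forest_mask, list(FOREST_CODES.values())).all():
            raise GridError("unknown forest_mask code")
        if not np.isin(self.region_mask, list(REGION_CODES.values())).all():
            raise GridError("unknown region_mask code")
        if not self.cell_area > 0:
            raise GridError("cell_area must be positive")
        return self


def grid_to_xarray(grid: CovariateGrid) -> xr.Dataset:
    names = GRID_COVARIATES + GRID_SOIL_LAYERS + GRID_MASKS
    data = {n: (("y", "x"), np.asarray(grid.layer(n), dtype=float)) for n in names}
    ds = xr.Dataset(data, attrs={"cell_area_m2": float(grid.cell_area)})
    return ds


def grid_from_xarray(ds: xr.Dataset) -> CovariateGrid:
    names = GRID_COVARIATES + GRID_SOIL_LAYERS + GRID_MASKS
    missing = [n for n in names if n not in ds]
    if missing:
        raise GridError(f"missing grid layer(s): {missing}")
    kwargs = {n: ds[n].values.copy() for n in names}
    for mask in GRID_MASKS + ["mineral"]:
        kwargs[mask] = np.asarray(np.rint(kwargs[mask]), dtype=int)
    grid = CovariateGrid(cell_area=float(ds.attrs["cell_area_m2"]), **kwargs)
    return grid.validate()


def write_grid(grid: CovariateGrid, path) -> None:
    """Write the grid as a NetCDF container (scipy backend, NetCDF-3)."""
    grid_to_xarray(grid).to_netcdf(path, engine="scipy")


def read_grid(path) -> CovariateGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        return grid_from_xarray(ds.load())


@dataclass
class GroupMeans:
    """Per-forest-type summary of one concentration response."""

    response: str
    mean: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]
    ratio_natural_to_planted: float
    f_statistic: float
    p_value: float


def group_means(ds: Dataset, response: str) -> GroupMeans:
    """Forest-type means +/- SE, the natural:planted ratio, and a one-way
    ANOVA F-test of the type difference."""
    if response not in ("maoc", "poc"):
        raise ValueError(f"response must be 'maoc' or 'poc', got {response!r}")
    df = ds.records.dropna(subset=[response])
    groups = {t: df.loc[df["forest_type"] == t, response].to_numpy()
              for t in FOREST_TYPES}
    for t, vals in groups.items():
        if len(vals) == 0:
            raise InsufficientDataError(f"no {t} records with non-missing {response}")
    mean = {t: float(v.mean()) for t, v in groups.items()}
    se = {t: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
          for t, v in groups.items()}
    f, p = stats.f_oneway(groups["natural"], groups["planted"])
    return GroupMeans(
        response=response, mean=mean, se=se,
        n={t: int(len(v)) for t, v in groups.items()},
        ratio_natural_to_planted=mean["natural"] / mean["planted"],
        f_statistic=float(f), p_value=float(p),
    )
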