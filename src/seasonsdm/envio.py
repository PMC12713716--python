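"""Gridded environmental stacks, occurrence handling and the collinearity screen.

The in-memory container is :class:`EnvStack`: a dictionary of 2-D layers keyed
by ``(variable, year, month)`` on a shared rectangular grid.  Grids are either
planar (coordinates in km, as produced by the synthetic landscape generator) or
geographic (degrees); the flag only switches the distance function used by the
pseudo-absence samplers and buffers, never the array handling.

Cell convention: cells are half-open, ``[x0 + j*c, x0 + (j+1)*c)``; a point on
an interior boundary belongs to the cell to its lower-left, which keeps cell
assignment deterministic.  Row 0 is the southernmost row.  No-data cells carry
NaN and are excluded from screening, prediction averages and regional means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from seasonsdm.errors import MissingLayerError, OutsideExtentError

logger = logging.getLogger(__name__)

#: Core variable names used throughout: minimum / maximum temperature (degC),
#: precipitation (mm), potential evapotranspiration (mm), vapour pressure
#: deficit (Pa), NDVI (unitless) and rainfed-corn cultivation area (kha/cell).
CORE_VARIABLES = ("MINTEMP", "MAXTEMP", "PRECIPI", "EVAPO", "VAPOR", "NDVI", "RFD")

#: Months merged for modelling: December-February (winter) and March-May
#: (spring) are pooled because too few presences exist for single-month
#: models; June-November are modelled individually.
DEFAULT_SEASON_BINS: dict[str, tuple[int, ...]] = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "June": (6,),
    "July": (7,),
    "August": (8,),
    "September": (9,),
    "October": (10,),
    "November": (11,),
}


def month_to_bin(season_bins: Mapping[str, Sequence[int]]) -> dict[int, str]:
    """Invert a season-bin mapping to month -> bin name."""
    out: dict[int, str] = {}
    for name, months in season_bins.items():
        for m in months:
            if m in out:
                raise ValueError(f"month {m} appears in two season bins")
            out[m] = name
    return out


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular raster grid.

    ``x0, y0`` are the coordinates of the outer lower-left corner; ``crs`` is
    ``"planar_km"`` (coordinates and cell size in km) or ``"geographic"``
    (degrees, distances measured on the sphere).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0
    crs: str = "planar_km"

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.crs not in ("planar_km", "geographic"):
            raise ValueError(f"unknown crs {self.crs!r}")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.cell_size,
            self.y0 + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) cell-center coordinates."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def cell_of(self, lon, lat) -> np.ndarray:
        """Vectorised point -> cell_id lookup (row-major ids).

        Boundary points belong to the lower-left cell; points on the outer
        lower/left edge belong to the first row/column.  Raises
        :class:`OutsideExtentError` for points outside the extent.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        tx = (lon - self.x0) / self.cell_size
        ty = (lat - self.y0) / self.cell_size
        if np.any(tx < 0) or np.any(ty < 0) or np.any(tx > self.n_cols) or np.any(ty > self.n_rows):
            raise OutsideExtentError("point(s) outside grid extent")
        col = np.where(tx <= 0, 0, np.ceil(tx) - 1).astype(int)
        row = np.where(ty <= 0, 0, np.ceil(ty) - 1).astype(int)
        return row * self.n_cols + col

    def center_of(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates for row-major cell ids."""
        cell_id = np.asarray(cell_id, dtype=int)
        row, col = np.divmod(cell_id, self.n_cols)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (row + 0.5) * self.cell_size
        return x, y


@dataclass
class EnvStack:
    """Monthly environmental layers on a shared grid.

    ``layers`` maps ``(variable, year, month)`` to a 2-D float array of shape
    ``(n_rows, n_cols)``.  A variable stored for a single year (the crop layer
    RFD, which is an average cultivation map replicated across years) is
    transparently served for any requested year.
    """

    grid: GridSpec
    layers: dict[tuple[str, int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for key, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.n_rows, self.grid.n_cols):
                raise ValueError(f"layer {key} shape {arr.shape} != grid shape")
            self.layers[key] = arr

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.layers}))

    def years(self, variable: str | None = None) -> tuple[int, ...]:
        keys = self.layers if variable is None else [k for k in self.layers if k[0] == variable]
        return tuple(sorted({k[1] for k in keys}))

    def months(self, variable: str | None = None) -> tuple[int, ...]:
        keys = self.layers if variable is None else [k for k in self.layers if k[0] == variable]
        return tuple(sorted({k[2] for k in keys}))

    def get_layer(self, variable: str, year: int, month: int) -> np.ndarray:
        """Layer lookup with single-year fallback for replicated variables."""
        key = (variable, year, month)
        if key in self.layers:
            return self.layers[key]
        yrs = self.years(variable)
        if len(yrs) == 1 and (variable, yrs[0], month) in self.layers:
            return self.layers[(variable, yrs[0], month)]
        raise MissingLayerError(variable, year, month)

    def has_layer(self, variable: str, year: int, month: int) -> bool:
        try:
            self.get_layer(variable, year, month)
            return True
        except MissingLayerError:
            return False

    # ------------------------------------------------------------------ I/O
    def to_netcdf(self, path) -> None:
        """Write the stack as a NetCDF file (one data variable per layer)."""
        import xarray as xr

        data = {
            f"{var}_{year:04d}_{month:02d}": (("y", "x"), arr)
            for (var, year, month), arr in sorted(self.layers.items())
        }
        xs, ys = self.grid.cell_centers()
        ds = xr.Dataset(data, coords={"x": xs, "y": ys})
        ds.attrs.update(
            n_rows=self.grid.n_rows,
            n_cols=self.grid.n_cols,
            cell_size=self.grid.cell_size,
            x0=self.grid.x0,
            y0=self.grid.y0,
            crs=self.grid.crs,
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
            a = ds.attrs
            grid = GridSpec(
                n_rows=int(a["n_rows"]),
                n_cols=int(a["n_cols"]),
                cell_size=float(a["cell_size"]),
                x0=float(a["x0"]),
                y0=float(a["y0"]),
                crs=str(a["crs"]),
            )
            layers = {}
            for name, da in ds.data_vars.items():
                var, year, month = name.rsplit("_", 2)
                layers[(var, int(year), int(month))] = np.asarray(da.values, dtype=float)
        return cls(grid=grid, layers=layers)


# --------------------------------------------------------------------------
# Occurrence handling
# --------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ["lon", "lat", "year", "month", "cell_id"]


def thin_occurrences(raw: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Thin raw occurrence records to one per (grid cell, month, year).

    Records outside the grid extent are dropped (count logged); the first
    record of each duplicated key is retained.  Returns a table with columns
    ``lon, lat, year, month, cell_id``.
    """
    required = {"lon", "lat", "year", "month"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw occurrence table lacks columns {sorted(missing)}")
    df = raw.reset_index(drop=True).copy()
    xmin, ymin, xmax, ymax = grid.extent
    inside = (
        (df["lon"] >= xmin) & (df["lon"] <= xmax) & (df["lat"] >= ymin) & (df["lat"] <= ymax)
    )
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("thin_occurrences: dropped %d record(s) outside grid extent", n_dropped)
        df = df[inside]
    if df.empty:
        return pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    df = df.copy()
    df["cell_id"] = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    df = df.drop_duplicates(subset=["cell_id", "year", "month"], keep="first")
    return df[OCCURRENCE_COLUMNS].reset_index(drop=True)


# --------------------------------------------------------------------------
# Rescaling
# --------------------------------------------------------------------------


def rescale_stack(
    stack: EnvStack,
    target_cell_size: float,
    *,
    aggregate_rules: Mapping[str, str] | None = None,
) -> EnvStack:
    """Bring all layers to a common target resolution.

    Aggregation (coarsening by an integer factor) uses the block mean for
    continuous variables; per-variable rules (``"mean"`` or ``"sum"``) can be
    supplied via ``aggregate_rules`` — an area total such as the crop layer is
    conserved with ``"sum"``.  Refinement (integer factor) uses bilinear
    interpolation of cell-center values.  Rescaling to the stack's own
    resolution returns an identical copy.
    """
    if not stack.layers:
        raise ValueError("empty stack")
    if target_cell_size <= 0:
        raise ValueError("target_cell_size must be positive")
    rules = dict(aggregate_rules or {})
    src = stack.grid.cell_size
    if np.isclose(target_cell_size, src):
        return EnvStack(grid=stack.grid, layers={k: v.copy() for k, v in stack.layers.items()})

    if target_cell_size > src:
        factor = target_cell_size / src
        if not np.isclose(factor, round(factor)):
            raise ValueError("coarsening requires an integer factor")
        f = int(round(factor))
        if stack.grid.n_rows % f or stack.grid.n_cols % f:
            raise ValueError("grid dimensions not divisible by aggregation factor")
        nr, nc = stack.grid.n_rows // f, stack.grid.n_cols // f
        grid = replace(stack.grid, n_rows=nr, n_cols=nc, cell_size=target_cell_size)
        layers = {}
        for (var, year, month), arr in stack.layers.items():
            blocks = arr.reshape(nr, f, nc, f)
            if rules.get(var, "mean") == "sum":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    out = np.nansum(blocks, axis=(1, 3))
                    out[np.all(np.isnan(blocks), axis=(1, 3))] = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    out = np.nanmean(blocks, axis=(1, 3))
            layers[(var, year, month)] = out
        return EnvStack(grid=grid, layers=layers)

    # refinement
    factor = src / target_cell_size
    if not np.isclose(factor, round(factor)):
        raise ValueError("refinement requires an integer factor")
    f = int(round(factor))
    nr, nc = stack.grid.n_rows * f, stack.grid.n_cols * f
    grid = replace(stack.grid, n_rows=nr, n_cols=nc, cell_size=target_cell_size)
    from scipy.interpolate import RegularGridInterpolator

    xs_src, ys_src = stack.grid.cell_centers()
    xs_dst, ys_dst = grid.cell_centers()
    gx, gy = np.meshgrid(xs_dst, ys_dst)
    pts = np.column_stack([gy.ravel(), gx.ravel()])
    layers = {}
    for (var, year, month), arr in stack.layers.items():
        interp = RegularGridInterpolator(
            (ys_src, xs_src), arr, method="linear", bounds_error=False, fill_value=None
        )
        out = interp(pts).reshape(nr, nc)
        if rules.get(var) == "sum":
            out = out / (f * f)  # conserve the area total
        layers[(var, year, month)] = out
    return EnvStack(grid=grid, layers=layers)


# --------------------------------------------------------------------------
# Point extraction
# --------------------------------------------------------------------------


def extract_env(
    stack: EnvStack, points: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Extract covariate values at point locations from matching monthly layers.

    Each point contributes one row; the value for a variable is the stored
    value of the grid cell containing the point, taken from the layer of the
    point's (year, month) — with the single-year fallback for replicated
    variables.  Raises for points outside the extent or for a missing layer
    (the error names the variable, year and month).
    """
    required = {"lon", "lat", "year", "month"}
    if required - set(points.columns):
        raise ValueError("points table needs lon, lat, year, month columns")
    pts = points.reset_index(drop=True)
    if pts.empty:
        return pts.assign(**{v: pd.Series(dtype=float) for v in variables})
    cell = (
        pts["cell_id"].to_numpy()
        if "cell_id" in pts.columns
        else stack.grid.cell_of(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    )
    row, col = np.divmod(np.asarray(cell, dtype=int), stack.grid.n_cols)
    out = pts.copy()
    for var in variables:
        vals = np.empty(len(pts))
        for (year, month), idx in pts.groupby(["year", "month"]).indices.items():
            layer = stack.get_layer(var, int(year), int(month))
            vals[idx] = layer[row[idx], col[idx]]
        out[var] = vals
    return out


# --------------------------------------------------------------------------
# Collinearity screen
# --------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    """Configuration of the seasonal Pearson collinearity screen.

    Variables with an averaged pairwise |r| at or above ``r_threshold`` in any
    season bin are removed iteratively; within an offending pair, the variable
    earliest in ``drop_priority`` goes first.  The default priority removes the
    derived variables (vapour-pressure deficit, maximum temperature) that are
    less commonly used in armyworm distribution models, keeping their sources.
    """

    r_threshold: float = 0.8
    drop_priority: tuple[str, ...] = ("VAPOR", "MAXTEMP")
    season_bins: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_BINS)
    )

    def __post_init__(self):
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must be in (0, 1]")
        month_to_bin(self.season_bins)  # validates disjointness


def _corr_matrix(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Pearson matrix; constant columns yield r = 0 with a warning."""
    sub = df[list(variables)].astype(float)
    constant = [v for v in variables if np.nanstd(sub[v].to_numpy()) == 0]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlations set to 0", stacklevel=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mat = sub.corr(method="pearson")
    mat = mat.fillna(0.0)
    np.fill_diagonal(mat.values, 1.0)
    return mat


def pearson_screen(
    datasets: Mapping[str, Sequence[pd.DataFrame]],
    config: ScreenConfig | None = None,
    variables: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, pd.DataFrame]]:
    """Seasonal collinearity screen over replicate covariate tables.

    ``datasets`` maps each season bin to its replicate covariate tables (one
    per pseudo-absence set).  Pearson matrices are computed per table and
    arithmetically averaged within each bin; variables are then removed
    iteratively — at each step the pair with the largest averaged |r| at or
    above the threshold in any bin loses its higher-priority member — until no
    pair exceeds the threshold.  Returns the retained variables (input order)
    and the averaged matrix per bin (computed on the full variable set).
    """
    config = config or ScreenConfig()
    if not datasets:
        raise ValueError("no datasets supplied")
    if variables is None:
        first = next(iter(datasets.values()))[0]
        variables = [
            c for c in first.columns if c not in ("lon", "lat", "year", "month", "cell_id", "label")
        ]
    variables = list(variables)
    matrices: dict[str, pd.DataFrame] = {}
    for bin_name, tables in datasets.items():
        if not tables:
            raise ValueError(f"season bin {bin_name!r} has no covariate tables")
        for t in tables:
            if len(t) < 2:
                raise ValueError(f"covariate table in bin {bin_name!r} has < 2 rows")
        mats = [_corr_matrix(t, variables) for t in tables]
        matrices[bin_name] = sum(m for m in mats) / len(mats)

    # deterministic removal priority: configured list first, then input order
    priority = [v for v in config.drop_priority if v in variables]
    priority += [v for v in variables if v not in priority]
    rank = {v: i for i, v in enumerate(priority)}

    kept = list(variables)
    while True:
        worst: tuple[float, str, str] | None = None
        for mat in matrices.values():
            sub = mat.loc[kept, kept].abs().to_numpy()
            np.fill_diagonal(sub, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] >= config.r_threshold and (worst is None or sub[i, j] > worst[0]):
                worst = (sub[i, j], kept[i], kept[j])
        if worst is None:
            break
        _, a, b = worst
        drop = a if rank[a] < rank[b] else b
        logger.info("pearson_screen: dropping %s (|r|=%.3f with %s)", drop, worst[0], a if drop == b else b)
        kept.remove(drop)
        if len(kept) < 2:
            break
    return kept, matrices
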