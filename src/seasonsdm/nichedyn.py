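"""Niche overlap and dynamics between two seasonal periods in PCA space.

The available environment is the pooled set of cells within a flight-distance
buffer of any presence, with covariates taken from each cell's month/year
layers.  A two-axis PCA of the standardised pooled background defines a shared
environment space; occurrence and background densities are estimated on an
R x R grid spanning the background score ranges with Gaussian kernels.  Within
the analog region (environments available to both periods) each period's
occupied niche is binarised by dropping the thinnest tail of its occurrence
density mass, and three indices summarise the comparison of a reference
period (here: non-outbreak months) against a comparison period (outbreak
months, June-September):

* stability  = |shared| / |reference occupied|      (stability + expansion = 1)
* expansion  = |reference only| / |reference occupied|
* unfilling  = |comparison only| / |comparison occupied|

One-dimensional occupancy profiles along single variables (availability and
occurrence densities, each rescaled to a maximum of 1) identify which
variables drive the seasonal differentiation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from seasonsdm.envio import EnvStack
from seasonsdm.errors import DegenerateDensityError
from seasonsdm.pabs import distance_km

logger = logging.getLogger(__name__)

OUTBREAK_MONTHS = (6, 7, 8, 9)

#: Background tables larger than this are subsampled (seeded) before KDE,
#: whose cost scales with n_samples x n_grid.
MAX_KDE_POINTS = 20_000


def buffer_background(
    presences: pd.DataFrame,
    stack: EnvStack,
    variables: Sequence[str],
    radius_km: float = 500.0,
) -> pd.DataFrame:
    """Environmental values of all cells within a buffer of any presence.

    For each (year, month) group of presences, the union of closed-ball
    buffers around that group's points is enumerated and the group's monthly
    layers are sampled at every union cell; rows from all years are pooled and
    tagged with their source month and year.
    """
    if presences.empty:
        raise ValueError("no presences")
    grid = stack.grid
    xs, ys = grid.cell_centers()
    cx = np.tile(xs, grid.n_rows)
    cy = np.repeat(ys, grid.n_cols)
    rows = []
    for (year, month), g in presences.groupby(["year", "month"]):
        inside = np.zeros(grid.n_cells, dtype=bool)
        for lon, lat in zip(g["lon"], g["lat"]):
            inside |= distance_km(grid, lon, lat, cx, cy) <= radius_km
        cells = np.flatnonzero(inside)
        if cells.size == 0:
            raise ValueError(f"empty buffer for {year}-{month:02d}")
        r, c = np.divmod(cells, grid.n_cols)
        bx, by = grid.center_of(cells)
        rec = {"cell_id": cells, "lon": bx, "lat": by, "year": int(year),
               "month": int(month)}
        for v in variables:
            rec[v] = stack.get_layer(v, int(year), int(month))[r, c]
        rows.append(pd.DataFrame(rec))
    out = pd.concat(rows, ignore_index=True)
    return out.dropna(subset=list(variables)).reset_index(drop=True)


@dataclass
class NicheSpace:
    """Two-axis PCA of the pooled, standardised background environment."""

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray  # (2, p), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    def transform(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project covariate rows onto the two PCA axes."""
        X = table[self.variables].to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
        Z = (X - self.means) / self.sds
        return Z @ self.components.T


def fit_niche_space(background: pd.DataFrame, variables: Sequence[str]) -> NicheSpace:
    """PCA (correlation scaled) of the pooled background of both periods.

    Constant variables are dropped with a warning; the first two axes define
    the shared niche space.
    """
    from sklearn.decomposition import PCA

    if len(background) < 3:
        raise ValueError("need at least 3 background rows")
    variables = list(variables)
    X = background[variables].to_numpy(dtype=float)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        warnings.warn(f"constant variable(s) dropped from PCA: {dropped}")
        variables = [v for v, k in zip(variables, keep) if k]
        X = X[:, keep]
        sds = sds[keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant variables")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    pca = PCA(n_components=2)
    pca.fit(Z)
    return NicheSpace(
        variables=variables,
        means=means,
        sds=sds,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class NicheGrid:
    """Kernel densities of occurrence and background on the shared score grid.

    ``z`` integrates to 1 over the window (occurrence density); ``background``
    is the availability density.  Grid cell centers are ``xs`` x ``ys``.
    """

    z: np.ndarray  # (R, R), rows = y axis
    background: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    period: str = ""

    @property
    def cell_area(self) -> float:
        return float((self.xs[1] - self.xs[0]) * (self.ys[1] - self.ys[0]))


def _kde_on_grid(pts: np.ndarray, gx: np.ndarray, gy: np.ndarray,
                 bw: str | float, rng: np.random.Generator | None) -> np.ndarray:
    if len(pts) > MAX_KDE_POINTS:
        rng = rng or np.random.default_rng(0)
        pts = pts[rng.choice(len(pts), MAX_KDE_POINTS, replace=False)]
    if len(pts) < 2 or np.allclose(pts.std(axis=0), 0):
        raise DegenerateDensityError("too few distinct points for a 2-D KDE")
    kde = gaussian_kde(pts.T, bw_method=bw)
    XX, YY = np.meshgrid(gx, gy)
    return kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(len(gy), len(gx))


def density_grid(
    scores: np.ndarray,
    background_scores: np.ndarray,
    R: int = 100,
    bandwidth_rule: str | float = "silverman",
    period: str = "",
    seed: int = 0,
    window_scores: np.ndarray | None = None,
) -> NicheGrid:
    """Gaussian-kernel occurrence and availability densities on an R x R grid.

    The window spans the background score ranges (or ``window_scores`` when
    given, e.g. the pooled background of both periods so two grids share one
    window); occurrence scores outside it are clipped with a warning.  The
    occurrence density is normalised to integrate to 1 over the window.
    """
    scores = np.asarray(scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 occurrence points")
    window = background_scores if window_scores is None else np.asarray(window_scores, dtype=float)
    lo = window.min(axis=0)
    hi = window.max(axis=0)
    if np.any(scores < lo) or np.any(scores > hi):
        warnings.warn("occurrence scores outside the background window were clipped")
        scores = np.clip(scores, lo, hi)
    gx = np.linspace(lo[0], hi[0], R)
    gy = np.linspace(lo[1], hi[1], R)
    rng = np.random.default_rng(seed)
    z = _kde_on_grid(scores, gx, gy, bandwidth_rule, rng)
    bg = _kde_on_grid(background_scores, gx, gy, bandwidth_rule, rng)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    total = z.sum() * cell
    if total <= 0:
        raise DegenerateDensityError("occurrence density integrates to zero")
    return NicheGrid(z=z / total, background=bg, xs=gx, ys=gy, period=period)


@dataclass
class DynamicIndices:
    """Niche stability / expansion / unfilling between two periods."""

    stability: float
    expansion: float
    unfilled: float

    def as_dict(self) -> dict[str, float]:
        return {"stability": self.stability, "expansion": self.expansion,
                "unfilled": self.unfilled}


def _occupied(z: np.ndarray, mask: np.ndarray, quantile: float) -> np.ndarray:
    """Binarise occupied niche: keep the densest cells holding (1 - quantile)
    of the in-mask occurrence density mass."""
    zm = np.where(mask, z, 0.0)
    total = zm.sum()
    if total <= 0:
        raise ValueError("empty occupied niche within the analog mask")
    if quantile <= 0:
        return zm > 0
    flat = np.sort(zm.ravel())[::-1]
    csum = np.cumsum(flat)
    cutoff_idx = int(np.searchsorted(csum, (1.0 - quantile) * total))
    threshold = flat[min(cutoff_idx, len(flat) - 1)]
    return zm >= max(threshold, np.finfo(float).tiny)


def niche_dynamics(
    z_comparison: NicheGrid,
    z_reference: NicheGrid,
    occupancy_threshold: float = 0.05,
    analog_eps: float = 1e-3,
) -> DynamicIndices:
    """Stability / expansion / unfilling from two occurrence-density grids.

    ``z_reference`` is the reference period (non-outbreak months in the
    seasonal analysis) and ``z_comparison`` the comparison period (outbreak
    months).  The analog mask keeps cells where both periods' background
    densities exceed ``analog_eps`` times their maximum; each period's
    occupied niche keeps the densest cells holding ``1 - occupancy_threshold``
    of its density mass.  By construction stability + expansion = 1.
    """
    if z_comparison.z.shape != z_reference.z.shape:
        raise ValueError("grids must share the same niche space resolution")
    mask = (z_comparison.background > analog_eps * z_comparison.background.max()) & (
        z_reference.background > analog_eps * z_reference.background.max()
    )
    occ_ref = _occupied(z_reference.z, mask, occupancy_threshold)
    occ_cmp = _occupied(z_comparison.z, mask, occupancy_threshold)
    n_ref = int(occ_ref.sum())
    n_cmp = int(occ_cmp.sum())
    overlap = int((occ_ref & occ_cmp).sum())
    return DynamicIndices(
        stability=overlap / n_ref,
        expansion=(n_ref - overlap) / n_ref,
        unfilled=(n_cmp - overlap) / n_cmp,
    )


@dataclass
class OccupancyCurves:
    """1-D availability and occurrence densities along one variable."""

    variable: str
    x: np.ndarray
    availability: dict[str, np.ndarray]  # period -> curve, max 1
    occupancy: dict[str, np.ndarray]  # period -> curve, max 1

    def occupied_segments(self, level: float = 0.05) -> dict[str, np.ndarray]:
        """Boolean masks along x: occupied by each period, plus overlap and
        period-unique segments."""
        periods = list(self.occupancy)
        occ = {p: self.occupancy[p] >= level for p in periods}
        if len(periods) == 2:
            a, b = periods
            occ["overlap"] = occ[a] & occ[b]
            occ[f"unique_{a}"] = occ[a] & ~occ[b]
            occ[f"unique_{b}"] = occ[b] & ~occ[a]
        return occ


def variable_occupancy(
    presence_values: Mapping[str, np.ndarray],
    background_values: Mapping[str, np.ndarray],
    variable: str,
    n_points: int = 256,
    bandwidth_rule: str | float = "silverman",
) -> OccupancyCurves:
    """Availability and occupancy profiles along a single variable.

    ``presence_values`` / ``background_values`` map each period name to that
    period's values of the variable.  Gaussian kernel densities are evaluated
    on a shared grid spanning the pooled background range and each curve is
    rescaled to a maximum of 1.  Constant values raise
    :class:`DegenerateDensityError`.
    """
    periods = list(presence_values)
    if set(background_values) != set(periods):
        raise ValueError("presence and background periods differ")
    pooled = np.concatenate([np.asarray(background_values[p], dtype=float) for p in periods])
    x = np.linspace(pooled.min(), pooled.max(), n_points)

    def curve(vals) -> np.ndarray:
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2 or np.std(vals) == 0:
            raise DegenerateDensityError(f"constant values for {variable!r}")
        d = gaussian_kde(vals, bw_method=bandwidth_rule)(x)
        return d / d.max()

    return OccupancyCurves(
        variable=variable,
        x=x,
        availability={p: curve(background_values[p]) for p in periods},
        occupancy={p: curve(presence_values[p]) for p in periods},
    )
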