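"""Suitability maps, interval classification, range polygons and optima summaries.

Predictions are population-level (year random intercept at its mean, zero):
the cellwise inverse-logit of the fitted linear predictor evaluated on the
month's layers.  Monthly maps are averaged across years and, by default,
across the replicate sub-models of the month.  The suitability index is
classified into equal intervals (0-10%, ..., 90-100%); occurrence ranges are
delineated by minimum convex polygons; and response-curve optima are compared
with the regional mean (TEA) and the presence-point mean (PEA) of each
variable per month or season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from seasonsdm.envio import DEFAULT_SEASON_BINS, EnvStack, GridSpec
from seasonsdm.errors import DegenerateGeometryError, MissingLayerError
from seasonsdm.sdmfit import FittedSDM

logger = logging.getLogger(__name__)


@dataclass
class SuitabilityMap:
    """A monthly habitat-suitability surface (values in [0, 1] or NaN)."""

    grid: GridSpec
    values: np.ndarray
    month: int
    provenance: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("map shape does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")


def predict_map(model: FittedSDM, stack: EnvStack, month: int, year: int) -> SuitabilityMap:
    """Cellwise inverse-logit prediction on one month's layers.

    No-data (NaN) cells propagate; a missing layer raises an error naming the
    variable, year and month.
    """
    env = {}
    for var in model.terms:
        if not stack.has_layer(var, year, month):
            raise MissingLayerError(var, year, month)
        env[var] = stack.get_layer(var, year, month)
    values = (
        model.predict(env)
        if model.terms
        else np.full((stack.grid.n_rows, stack.grid.n_cols), model.predict({}))
    )
    return SuitabilityMap(
        grid=stack.grid,
        values=values,
        month=month,
        provenance={"years": [year], "n_models": 1},
    )


def average_maps(maps: Sequence[SuitabilityMap]) -> SuitabilityMap:
    """Cellwise arithmetic mean, ignoring no-data cells."""
    if not maps:
        raise ValueError("no maps to average")
    months = {m.month for m in maps}
    if len(months) > 1:
        raise ValueError(f"cannot average maps of different months {sorted(months)}")
    grid = maps[0].grid
    for m in maps:
        if m.grid != grid:
            raise ValueError("maps share no common grid")
    stackv = np.stack([m.values for m in maps])
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stackv, axis=0)
    years = sorted({y for m in maps for y in m.provenance.get("years", [])})
    n_models = sum(m.provenance.get("n_models", 1) for m in maps)
    return SuitabilityMap(grid, mean, maps[0].month,
                          {"years": years, "n_models": n_models})


def classify_map(smap: SuitabilityMap, n_bins: int = 10) -> np.ndarray:
    """Equal-interval classification: bin i covers [i/n, (i+1)/n), top bin
    closed at 1.  No-data cells stay NaN.  Idempotent under re-binning."""
    v = smap.values
    out = np.where(np.isfinite(v), np.minimum(np.floor(n_bins * v), n_bins - 1), np.nan)
    return out


def min_convex_polygon(points: pd.DataFrame, month: int | None = None) -> np.ndarray:
    """Minimum convex polygon around occurrence points (optionally one month).

    Returns hull vertices (k, 2) in counter-clockwise order; fewer than three
    distinct non-collinear points raise :class:`DegenerateGeometryError`.
    """
    from scipy.spatial import ConvexHull, QhullError

    df = points if month is None else points[points["month"] == month]
    xy = np.unique(df[["lon", "lat"]].to_numpy(dtype=float), axis=0)
    if len(xy) < 3:
        raise DegenerateGeometryError(f"need >= 3 distinct points, got {len(xy)}")
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    verts = xy[hull.vertices]  # ConvexHull orders 2-D vertices counter-clockwise
    return verts


def response_optimum(
    model: FittedSDM, variable: str, value_range: tuple[float, float]
) -> tuple[float, bool]:
    """Peak of the partial-dependence response curve for one variable.

    Other covariates sit at their training means (standardised zero).  With a
    negative quadratic coefficient the peak is the parabola vertex
    ``-b1/(2 b2)`` back-transformed to the data scale; when the vertex falls
    outside ``value_range``, or the response is monotone, the maximising range
    endpoint is returned with the boundary flag set.
    """
    if variable not in model.terms:
        raise KeyError(f"variable {variable!r} not retained in model")
    lo, hi = value_range
    b1 = model.coef[variable]
    b2 = model.coef.get(f"{variable}^2", 0.0)
    mu, s = model.means[variable], model.sds[variable]
    if b2 < 0:
        opt = mu + s * (-b1 / (2.0 * b2))
        if lo <= opt <= hi:
            return float(opt), False
    # boundary case: evaluate the quadratic at both endpoints

    def eta(x):
        z = (x - mu) / s
        return b1 * z + b2 * z * z

    return (float(lo), True) if eta(lo) >= eta(hi) else (float(hi), True)


def landscape_range(stack: EnvStack, variable: str, months: Sequence[int]) -> tuple[float, float]:
    """Min/max of a variable over all layers of the given months (all years)."""
    vals = []
    for (var, _y, m), arr in stack.layers.items():
        if var == variable and m in months:
            finite = arr[np.isfinite(arr)]
            if finite.size:
                vals.append((finite.min(), finite.max()))
    if not vals:
        raise MissingLayerError(variable, -1, months[0])
    return float(min(v[0] for v in vals)), float(max(v[1] for v in vals))


def optima_summary(
    models: Mapping[str, Sequence[FittedSDM]],
    stack: EnvStack,
    presences: pd.DataFrame,
    variables: Sequence[str],
    season_bins: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """OEA / TEA / PEA comparison per variable and period.

    ``models`` maps each period (season-bin name) to its replicate sub-models.
    OEA is the mean response-curve optimum over the sub-models that retain the
    variable (missing when none does); boundary optima are flagged but still
    averaged.  TEA is the mean over all non-missing cells of the period's
    layers across years; PEA the mean at the period's presence points.  Returns
    columns ``variable, period, OEA, TEA, PEA, n_models, boundary_fraction``.
    """
    season_bins = dict(season_bins or DEFAULT_SEASON_BINS)
    from seasonsdm.envio import extract_env

    rows = []
    for period, sub_models in models.items():
        months = list(season_bins[period])
        pres = presences[presences["month"].isin(months)]
        for var in variables:
            vrange = landscape_range(stack, var, months)
            optima, boundary = [], []
            for m in sub_models:
                if var in m.terms:
                    o, b = response_optimum(m, var, vrange)
                    optima.append(o)
                    boundary.append(b)
            layers = [
                arr
                for (v, _y, mo), arr in stack.layers.items()
                if v == var and mo in months
            ]
            tea = float(np.nanmean(np.concatenate([a.ravel() for a in layers])))
            if len(pres):
                pea = float(extract_env(stack, pres, [var])[var].mean())
            else:
                pea = np.nan
            rows.append(
                {
                    "variable": var,
                    "period": period,
                    "OEA": float(np.mean(optima)) if optima else np.nan,
                    "TEA": tea,
                    "PEA": pea,
                    "n_models": len(optima),
                    "boundary_fraction": float(np.mean(boundary)) if boundary else np.nan,
                }
            )
    return pd.DataFrame(rows)
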