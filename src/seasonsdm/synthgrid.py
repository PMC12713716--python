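"""Synthetic monthly landscapes and a virtual species with a known niche.

The generator emulates the structure of the real modelling inputs: seven
monthly environmental variables on a shared grid over several years, with

* a smooth sinusoidal seasonal cycle per variable (configurable peak month),
* a north-south (latitudinal) gradient,
* a fixed smooth spatial texture plus independent per-layer noise and a small
  per-year offset (so a year random intercept is estimable),
* engineered collinearity: maximum temperature is generated from minimum
  temperature, and vapour-pressure deficit from evapotranspiration, with a
  configurable target Pearson r (defaults reproduce the |r| >= 0.8 screen),
* a crop layer (RFD) that is non-negative, zero outside the growing season and
  stored for a single replicated year, like an average cultivation map.

The virtual species has a logistic occurrence probability with linear and
quadratic (bell-shaped) responses to known optima — the same functional family
the distribution models fit, so parameter recovery is well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from seasonsdm.envio import EnvStack, GridSpec

__all__ = [
    "VariableSpec",
    "LandscapeConfig",
    "VirtualSpecies",
    "generate_env_stack",
    "sample_occurrences",
    "default_virtual_species",
]


@dataclass(frozen=True)
class VariableSpec:
    """Generation parameters of one base environmental variable.

    ``value = mean + seasonal_amplitude*cos(2*pi*(month-peak_month)/12)
    + latitudinal_gradient*(y - y_mid) + texture + year_offset + noise``,
    clipped to ``[clip_min, clip_max]`` where given.  Units follow the
    variable (degC, mm, Pa, NDVI index, kha per cell).
    """

    mean: float
    seasonal_amplitude: float
    peak_month: float = 7.0
    latitudinal_gradient: float = 0.0  # units per km northward
    noise_sd: float = 1.0
    texture_sd: float = 0.0  # sd of the static smooth spatial field
    clip_min: float | None = None
    clip_max: float | None = None


def _default_variables() -> dict[str, VariableSpec]:
    # Magnitudes loosely follow temperate-zone monthly climatologies; the
    # latitudinal gradients and spatial textures are strong enough that every
    # 500-km buffer spans clearly contrasting environments, which one-class
    # environmental profiling requires of a study region.
    return {
        "MINTEMP": VariableSpec(10.0, 12.0, peak_month=7, latitudinal_gradient=-0.018,
                                noise_sd=1.0, texture_sd=2.25),
        "PRECIPI": VariableSpec(80.0, 30.0, peak_month=6, latitudinal_gradient=0.015,
                                noise_sd=12.0, texture_sd=22.5, clip_min=0.0),
        "EVAPO": VariableSpec(90.0, 45.0, peak_month=7, latitudinal_gradient=-0.03,
                              noise_sd=8.0, texture_sd=15.0, clip_min=0.0),
        "NDVI": VariableSpec(0.45, 0.25, peak_month=7, latitudinal_gradient=-0.00015,
                             noise_sd=0.04, texture_sd=0.09, clip_min=0.0, clip_max=1.0),
    }


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    ``collinearity_targets`` lists ``(derived, source, target_r, offset,
    scale)`` tuples: the derived layer is ``offset + scale*source + noise``
    with the noise standard deviation calibrated so the within-layer Pearson
    correlation equals ``target_r``.  ``crop_season`` is the set of months with
    a non-zero crop layer.
    """

    n_rows: int = 60
    n_cols: int = 60
    cell_size_km: float = 25.0
    years: tuple[int, ...] = (2014, 2015, 2016)
    variables: Mapping[str, VariableSpec] = field(default_factory=_default_variables)
    collinearity_targets: tuple[tuple[str, str, float, float, float], ...] = (
        ("MAXTEMP", "MINTEMP", 0.9, 9.0, 1.0),
        ("VAPOR", "EVAPO", 0.9, 250.0, 8.0),
    )
    crop_season: frozenset[int] = frozenset({5, 6, 7, 8, 9, 10})
    crop_peak_month: float = 7.5
    crop_mean: float = 3.0  # kha per cell at seasonal peak
    year_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("grid must be at least 10x10")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if len(self.years) == 0:
            raise ValueError("years list is empty")
        for derived, source, r, *_ in self.collinearity_targets:
            if not (0 < r <= 1):
                raise ValueError(f"target_r for {derived}~{source} must be in (0, 1]")
            if source not in self.variables:
                raise ValueError(f"collinearity source {source!r} not among base variables")
        if not set(self.crop_season) <= set(range(1, 13)):
            raise ValueError("crop_season must be a subset of months 1..12")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows, n_cols=self.n_cols, cell_size=self.cell_size_km, crs="planar_km"
        )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Zero-mean smooth random surface with approximately the requested sd."""
    if sd == 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 12)
    s = raw.std()
    return raw * (sd / s) if s > 0 else np.zeros(shape)


def generate_env_stack(config: LandscapeConfig) -> EnvStack:
    """Generate the full synthetic monthly stack for all configured years.

    Deterministic for a fixed config (identical seed gives a bit-identical
    stack).  The crop layer ``RFD`` is produced for the first configured year
    only and served for every year through the stack's single-year fallback.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    _, ys = grid.cell_centers()
    y_dev = (ys - ys.mean())[:, None] * np.ones((1, grid.n_cols))

    textures = {
        var: _smooth_field(rng, (grid.n_rows, grid.n_cols), spec.texture_sd)
        for var, spec in sorted(config.variables.items())
    }
    year_effects = {
        var: {yr: rng.normal(0.0, config.year_effect_sd) for yr in config.years}
        for var in sorted(config.variables)
    }
    crop_texture = _smooth_field(rng, (grid.n_rows, grid.n_cols), 1.0)

    layers: dict[tuple[str, int, int], np.ndarray] = {}
    for var, spec in sorted(config.variables.items()):
        for year in config.years:
            for month in range(1, 13):
                seasonal = spec.mean + spec.seasonal_amplitude * np.cos(
                    2 * np.pi * (month - spec.peak_month) / 12.0
                )
                arr = (
                    seasonal
                    + spec.latitudinal_gradient * y_dev
                    + textures[var]
                    + year_effects[var][year]
                    + rng.normal(0.0, spec.noise_sd, size=(grid.n_rows, grid.n_cols))
                )
                if spec.clip_min is not None or spec.clip_max is not None:
                    arr = np.clip(arr, spec.clip_min, spec.clip_max)
                layers[(var, year, month)] = arr

    # derived collinear variables: noise sd set from the source layer's spatial
    # sd so the within-layer correlation hits the target r
    for derived, source, target_r, offset, scale in config.collinearity_targets:
        for year in config.years:
            for month in range(1, 13):
                src = layers[(source, year, month)]
                sd_noise = abs(scale) * src.std() * np.sqrt(1.0 / target_r**2 - 1.0)
                layers[(derived, year, month)] = (
                    offset
                    + scale * src
                    + rng.normal(0.0, sd_noise, size=src.shape)
                )

    # crop layer: one replicated year, zero outside the growing season
    rfd_year = config.years[0]
    months_sorted = sorted(config.crop_season)
    for month in range(1, 13):
        if month not in config.crop_season:
            layers[("RFD", rfd_year, month)] = np.zeros((grid.n_rows, grid.n_cols))
            continue
        # within-season bell profile peaking at crop_peak_month
        span = max(months_sorted[-1] - months_sorted[0], 1)
        profile = np.exp(-0.5 * ((month - config.crop_peak_month) / (span / 3.0)) ** 2)
        base = config.crop_mean * profile * np.exp(0.6 * crop_texture)
        layers[("RFD", rfd_year, month)] = np.clip(
            base + rng.normal(0.0, 0.1 * config.crop_mean, size=base.shape), 0.0, None
        )

    return EnvStack(grid=grid, layers=layers)


@dataclass
class VirtualSpecies:
    """A species whose true occurrence probability is a quadratic logistic.

    ``coefficients`` maps a variable name to ``(linear, quadratic)`` on the raw
    variable scale; quadratic terms must be non-positive so responses are
    bell-shaped.  Occurrence probability at a cell is
    ``expit(intercept + sum_v b1_v x_v + b2_v x_v^2)``, thinned by
    ``detection_rate``.
    """

    intercept: float
    coefficients: Mapping[str, tuple[float, float]]
    detection_rate: float = 1.0

    def __post_init__(self):
        if not (0 < self.detection_rate <= 1):
            raise ValueError("detection_rate must be in (0, 1]")
        for var, (_, b2) in self.coefficients.items():
            if b2 > 0:
                raise ValueError(f"quadratic coefficient for {var} must be <= 0")

    @property
    def known_optima(self) -> dict[str, float]:
        """True response-curve peaks, ``-b1/(2*b2)`` where the quadratic < 0."""
        return {
            var: -b1 / (2.0 * b2)
            for var, (b1, b2) in self.coefficients.items()
            if b2 < 0
        }

    def suitability(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        """Logistic suitability from a mapping of variable -> array."""
        eta = np.full_like(np.asarray(env[next(iter(self.coefficients))], dtype=float),
                           self.intercept)
        for var, (b1, b2) in self.coefficients.items():
            x = np.asarray(env[var], dtype=float)
            eta = eta + b1 * x + b2 * x * x
        return expit(eta)

    def suitability_grid(self, stack: EnvStack, year: int, month: int) -> np.ndarray:
        env = {v: stack.get_layer(v, year, month) for v in self.coefficients}
        return self.suitability(env)


def default_virtual_species(peak_eta: float = 2.0) -> VirtualSpecies:
    """The default study species: a warm-adapted, vegetation-associated insect.

    The species is cold-limited: its thermal optimum (minimum temperature
    28 degC) lies above the mid-summer landscape mean, so warming months open
    the northern half of the landscape while the south never overheats -- the
    suitable range expands into mid-summer and contracts in autumn, the
    seasonal pattern of a migratory pest.  Responses to NDVI (optimum 0.7) and
    evapotranspiration (optimum 120 mm) are broad and secondary.  ``peak_eta``
    sets the logit at the joint optimum (2.0 -> max suitability about 0.88).
    """
    coefficients = {
        "MINTEMP": (-2 * (-0.0247) * 28.0, -0.0247),
        "NDVI": (-2 * (-8.0) * 0.70, -8.0),
        "EVAPO": (-2 * (-0.0008) * 120.0, -0.0008),
    }
    peak_contrib = sum(b1 * (-b1 / (2 * b2)) + b2 * (-b1 / (2 * b2)) ** 2
                       for b1, b2 in coefficients.values())
    return VirtualSpecies(
        intercept=peak_eta - peak_contrib,
        coefficients=coefficients,
        detection_rate=0.8,
    )


def sample_occurrences(
    species: VirtualSpecies,
    stack: EnvStack,
    n_per_month: Mapping[int, int],
    seed: int,
) -> pd.DataFrame:
    """Sample thinned presence records from the virtual species.

    For every configured year and each month with a positive count, cells are
    drawn without replacement with probability proportional to suitability x
    detection rate, giving at most one record per (cell, month, year).  Raises
    if a month has fewer cells with non-zero sampling weight than requested.
    Returns ``lon, lat, year, month, cell_id`` (cell-center coordinates).
    """
    if any(n < 0 for n in n_per_month.values()):
        raise ValueError("n_per_month counts must be >= 0")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    years = stack.years(next(iter(species.coefficients)))
    rows = []
    for year in years:
        for month in sorted(n_per_month):
            n = n_per_month[month]
            if n == 0:
                continue
            suit = species.suitability_grid(stack, year, month)
            w = np.nan_to_num(suit.ravel() * species.detection_rate, nan=0.0)
            eligible = np.count_nonzero(w)
            if eligible < n:
                raise ValueError(
                    f"month {month}, year {year}: requested {n} occurrences but only "
                    f"{eligible} cells have non-zero suitability"
                )
            cells = rng.choice(grid.n_cells, size=n, replace=False, p=w / w.sum())
            x, y = grid.center_of(cells)
            rows.append(
                pd.DataFrame(
                    {"lon": x, "lat": y, "year": year, "month": month, "cell_id": cells}
                )
            )
    if not rows:
        return pd.DataFrame(columns=["lon", "lat", "year", "month", "cell_id"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["year", "month", "cell_id"], ignore_index=True)
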