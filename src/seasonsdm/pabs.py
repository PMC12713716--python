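"""Pseudo-absence generation: random sampling (RS) and environmental profiling (RSEP).

Both samplers draw, for every presence record, one pseudo-absence cell within a
flight-distance buffer (default 500 km — the approximate maximum displacement
of an individual armyworm moth) around that presence, excluding all presence
cells of the same seasonal subset.  RS picks uniformly among the eligible
cells.  RSEP first draws a pool of candidate background cells per presence,
scores each candidate with a one-class support vector machine trained on the
(standardised) presence covariates of the subset, and keeps only candidates
the classifier labels as outliers — i.e. environmentally dissimilar to the
presence data (similarity 0 under the inlier/outlier rule).

Distances are Euclidean between cell centers on planar grids and great-circle
(haversine) on geographic grids; the buffer is a closed ball.  Pseudo-absences
inherit the (year, month) of their presence so covariates come from matching
layers.  Within a replicate set each (cell, year, month) is used at most once
(the same rule occurrence thinning applies to presences); different sets are
independent draws and may reuse cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from seasonsdm.envio import (
    DEFAULT_SEASON_BINS,
    EnvStack,
    GridSpec,
    extract_env,
    month_to_bin,
)
from seasonsdm.errors import (
    InsufficientCandidatesError,
    NoDissimilarCandidateError,
)

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_km(grid: GridSpec, lon1, lat1, lon2, lat2) -> np.ndarray:
    """Distance in km under the grid's CRS (planar Euclidean or haversine)."""
    if grid.crs == "geographic":
        return haversine_km(lon1, lat1, lon2, lat2)
    return np.hypot(np.asarray(lon2, float) - lon1, np.asarray(lat2, float) - lat1)


@dataclass
class SamplerConfig:
    """Shared configuration of the RS and RSEP samplers.

    ``radius_km`` is the buffer radius around each presence; ``n_sets`` the
    number of replicate pseudo-absence sets; ``candidates_per_presence`` the
    background pool size per presence for RSEP.  The one-class SVM uses an RBF
    kernel with ``nu`` (expected outlier fraction among presences) and sklearn
    ``gamma`` (``"scale"`` = 1/(p * var)); inputs are z-standardised with
    presence means/sds.
    """

    radius_km: float = 500.0
    n_sets: int = 5
    candidates_per_presence: int = 30
    kernel: str = "rbf"
    nu: float = 0.1
    gamma: str | float = "scale"
    max_resample_attempts: int = 10
    seed: int = 0
    season_bins: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_BINS)
    )

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.candidates_per_presence < 1:
            raise ValueError("candidates_per_presence must be >= 1")


def _prepare(presences: pd.DataFrame, stack: EnvStack, config: SamplerConfig):
    """Common precomputation: subset tags, per-presence eligible cells."""
    if presences.empty:
        raise ValueError("no presence records")
    grid = stack.grid
    if config.radius_km < grid.cell_size and grid.crs == "planar_km":
        raise ValueError("degenerate buffer: radius smaller than one cell")
    pres = presences.reset_index(drop=True).copy()
    if "cell_id" not in pres.columns:
        pres["cell_id"] = grid.cell_of(pres["lon"].to_numpy(), pres["lat"].to_numpy())
    m2b = month_to_bin(config.season_bins)
    pres["subset"] = pres["month"].map(m2b)
    if pres["subset"].isna().any():
        bad = sorted(pres.loc[pres["subset"].isna(), "month"].unique())
        raise ValueError(f"months {bad} not covered by season_bins")

    xs, ys = grid.cell_centers()
    cx = np.tile(xs, grid.n_rows)
    cy = np.repeat(ys, grid.n_cols)

    # eligible cells per presence: closed ball, presence cells of the same
    # subset excluded
    subset_cells = {s: set(g["cell_id"]) for s, g in pres.groupby("subset")}
    eligible: list[np.ndarray] = []
    for lon, lat, subset in zip(pres["lon"], pres["lat"], pres["subset"]):
        d = distance_km(grid, lon, lat, cx, cy)
        cells = np.flatnonzero(d <= config.radius_km)
        excl = subset_cells[subset]
        eligible.append(cells[~np.isin(cells, list(excl))])

    # precondition: per subset, the buffer union must hold at least twice the
    # subset's presence count in non-presence cells
    for subset, g in pres.groupby("subset"):
        union = set()
        for i in g.index:
            union.update(eligible[i].tolist())
        if len(union) < 2 * len(g):
            raise InsufficientCandidatesError(
                f"subset {subset!r}: buffer union has {len(union)} non-presence cells "
                f"for {len(g)} presences (need >= {2 * len(g)})"
            )
    return pres, eligible


def _assemble(pres: pd.DataFrame, grid: GridSpec, chosen: np.ndarray, set_id: int, method: str) -> pd.DataFrame:
    x, y = grid.center_of(chosen)
    out = pd.DataFrame(
        {
            "lon": x,
            "lat": y,
            "year": pres["year"].to_numpy(),
            "month": pres["month"].to_numpy(),
            "cell_id": chosen,
            "set_id": set_id,
            "method": method,
            "label": 0,
        }
    )
    out.attrs["set_id"] = set_id
    out.attrs["method"] = method
    return out


def sample_rs(
    presences: pd.DataFrame, stack: EnvStack, config: SamplerConfig | None = None
) -> list[pd.DataFrame]:
    """Random-sampling pseudo-absences: one uniform draw per presence.

    Returns ``n_sets`` tables, each with exactly one pseudo-absence per
    presence (matching year and month), no collisions with presence cells of
    the same seasonal subset, no repeated (cell, year, month) within a set, and
    all points within ``radius_km`` of their presence.
    """
    config = config or SamplerConfig()
    pres, eligible = _prepare(presences, stack, config)
    rng = np.random.default_rng(config.seed)
    grid = stack.grid
    sets = []
    for set_id in range(config.n_sets):
        # one use per (cell, year, month) within a set, mirroring thinning
        used: dict[tuple, set[int]] = {}
        chosen = np.empty(len(pres), dtype=int)
        for i in range(len(pres)):
            key = (pres.at[i, "subset"], int(pres.at[i, "year"]), int(pres.at[i, "month"]))
            taken = used.setdefault(key, set())
            pool = eligible[i]
            pool = pool[~np.isin(pool, list(taken))] if taken else pool
            if len(pool) == 0:
                raise InsufficientCandidatesError(
                    f"presence {i}: no eligible cell left within {config.radius_km} km"
                )
            c = int(rng.choice(pool))
            chosen[i] = c
            taken.add(c)
        sets.append(_assemble(pres, grid, chosen, set_id, "RS"))
    return sets


def fit_presence_profiles(
    presences: pd.DataFrame,
    stack: EnvStack,
    variables: Sequence[str],
    config: SamplerConfig,
) -> dict[str, tuple[OneClassSVM, np.ndarray, np.ndarray]]:
    """Train one one-class SVM per seasonal subset on presence covariates.

    Returns subset -> (fitted classifier, means, sds) where means/sds are the
    presence standardisation constants reused to score candidates.
    """
    m2b = month_to_bin(config.season_bins)
    pres = presences.reset_index(drop=True).copy()
    pres["subset"] = pres["month"].map(m2b)
    cov = extract_env(stack, pres, variables)
    profiles = {}
    for subset, g in cov.groupby(pres["subset"]):
        X = g[list(variables)].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = OneClassSVM(kernel=config.kernel, nu=config.nu, gamma=config.gamma)
        clf.fit((X - mu) / sd)
        profiles[subset] = (clf, mu, sd)
    return profiles


def sample_rsep(
    presences: pd.DataFrame,
    stack: EnvStack,
    variables: Sequence[str],
    config: SamplerConfig | None = None,
) -> list[pd.DataFrame]:
    """Environmentally profiled pseudo-absences.

    Per presence, ``candidates_per_presence`` background cells are drawn
    uniformly within the buffer; each candidate's covariates (from the
    presence's year/month layers) are scored by the subset's one-class SVM, and
    one candidate with similarity 0 (classifier outlier, decision value < 0) is
    selected at random.  If a draw yields no dissimilar unused candidate, the
    pool is redrawn up to ``max_resample_attempts`` times before raising — a
    landscape whose buffer holds no contrasting environment is an error, not a
    silent fallback.
    """
    config = config or SamplerConfig()
    pres, eligible = _prepare(presences, stack, config)
    profiles = fit_presence_profiles(presences, stack, variables, config)
    rng = np.random.default_rng(config.seed + 1)
    grid = stack.grid

    # direct (row, col) lookup of covariates, faster than DataFrame extraction
    nc = grid.n_cols

    def covariates_at(cells: np.ndarray, year: int, month: int) -> np.ndarray:
        r, c = np.divmod(cells, nc)
        return np.column_stack(
            [stack.get_layer(v, year, month)[r, c] for v in variables]
        )

    sets = []
    for set_id in range(config.n_sets):
        used: dict[tuple, set[int]] = {}
        chosen = np.empty(len(pres), dtype=int)
        for i in range(len(pres)):
            subset = pres.at[i, "subset"]
            year = int(pres.at[i, "year"])
            month = int(pres.at[i, "month"])
            clf, mu, sd = profiles[subset]
            taken = used.setdefault((subset, year, month), set())
            pool = eligible[i]
            if taken:
                pool = pool[~np.isin(pool, list(taken))]
            if len(pool) == 0:
                raise InsufficientCandidatesError(
                    f"presence {i}: no eligible cell left within {config.radius_km} km"
                )
            picked = -1
            for _ in range(config.max_resample_attempts):
                k = min(config.candidates_per_presence, len(pool))
                cand = rng.choice(pool, size=k, replace=False)
                Z = (covariates_at(cand, year, month) - mu) / sd
                dissimilar = cand[clf.decision_function(Z) < 0]
                if len(dissimilar) > 0:
                    picked = int(rng.choice(dissimilar))
                    break
            if picked < 0:
                # random pools can miss sparse outlier cells; before declaring
                # the buffer environmentally homogeneous, scan it exhaustively
                Z = (covariates_at(pool, year, month) - mu) / sd
                dissimilar = pool[clf.decision_function(Z) < 0]
                if len(dissimilar) > 0:
                    picked = int(rng.choice(dissimilar))
                else:
                    raise NoDissimilarCandidateError(
                        f"presence {i} (subset {subset!r}, {year}-{month:02d}): no "
                        f"environmentally dissimilar cell within {config.radius_km} km "
                        f"after {config.max_resample_attempts} candidate redraws"
                    )
            chosen[i] = picked
            taken.add(picked)
        sets.append(_assemble(pres, grid, chosen, set_id, "RSEP"))
    return sets
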