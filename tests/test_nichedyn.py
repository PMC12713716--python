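"""Niche space, density grids, dynamics indices and occupancy curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

from seasonsdm.envio import EnvStack, GridSpec
from seasonsdm.errors import DegenerateDensityError
from seasonsdm.nichedyn import (
    DynamicIndices,
    NicheGrid,
    buffer_background,
    density_grid,
    fit_niche_space,
    niche_dynamics,
    variable_occupancy,
)

VARS = ["MINTEMP", "PRECIPI", "EVAPO", "NDVI", "RFD"]


def _point_at(grid, cell, year=2014, month=7):
    x, y = grid.center_of(np.array([cell]))
    return pd.DataFrame({"lon": x, "lat": y, "year": [year], "month": [month],
                         "cell_id": [cell]})


class TestBufferBackground:
    def test_tiny_radius_returns_presence_cell_only(self, small_stack):
        pres = _point_at(small_stack.grid, 100)
        bg = buffer_background(pres, small_stack, ["MINTEMP"], radius_km=1.0)
        assert len(bg) == 1
        assert bg["cell_id"].iloc[0] == 100

    def test_disjoint_buffers_sum_cell_counts(self, small_stack):
        grid = small_stack.grid
        pres = pd.concat([_point_at(grid, 0), _point_at(grid, grid.n_cells - 1)],
                         ignore_index=True)
        r = 50.0
        bg = buffer_background(pres, small_stack, ["MINTEMP"], radius_km=r)
        # direct enumeration oracle
        xs = np.tile(grid.cell_centers()[0], grid.n_rows)
        ys = np.repeat(grid.cell_centers()[1], grid.n_cols)
        count = 0
        for cell in (0, grid.n_cells - 1):
            px, py = grid.center_of(np.array([cell]))
            count += int(np.sum(np.hypot(xs - px, ys - py) <= r))
        assert len(bg) == count

    def test_all_cells_within_radius_of_a_presence(self, small_stack, small_presences):
        r = 120.0
        sub = small_presences.head(20)
        bg = buffer_background(sub, small_stack, ["MINTEMP"], radius_km=r)
        bx, by = small_stack.grid.center_of(bg["cell_id"].to_numpy())
        for _, row in bg.iterrows():
            g = sub[(sub.year == row.year) & (sub.month == row.month)]
            d = np.hypot(g["lon"] - row["lon"], g["lat"] - row["lat"])
            assert (d <= r).any()

    def test_rows_tagged_with_source_month(self, small_stack, small_presences):
        bg = buffer_background(small_presences.head(30), small_stack, ["MINTEMP"], 80.0)
        assert set(bg["month"]) <= set(small_presences.head(30)["month"])


class TestNicheSpace:
    def test_two_identical_variables_put_all_variance_on_axis_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        bg = pd.DataFrame({"a": x, "b": 2 * x + 1})
        space = fit_niche_space(bg, ["a", "b"])
        assert space.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_axes_orthonormal_and_variance_ordered(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        space = fit_niche_space(bg, list("abcd"))
        assert np.allclose(space.components @ space.components.T, np.eye(2), atol=1e-10)
        assert space.explained_variance[0] >= space.explained_variance[1]

    def test_hand_computed_eigenstructure(self):
        # 4x3 matrix whose standardised covariance has a known leading axis
        bg = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0],
             "c": [1.0, -1.0, -1.0, 1.0]}
        )
        space = fit_niche_space(bg, ["a", "b", "c"])
        # a and b are identical after standardisation and independent of c:
        # leading axis is (1,1,0)/sqrt(2) with eigenvalue 2, second axis is c
        lead = np.abs(space.components[0])
        assert lead[:2] == pytest.approx([1 / np.sqrt(2)] * 2)
        assert lead[2] == pytest.approx(0.0, abs=1e-10)
        assert space.explained_variance[0] == pytest.approx(2.0 * 4 / 3)  # sklearn ddof=1 scaling

    def test_constant_variable_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50),
                           "c": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            space = fit_niche_space(bg, ["a", "b", "c"])
        assert space.variables == ["a", "b"]


class TestDensityGrid:
    def test_single_cluster_mode_at_its_location(self):
        rng = np.random.default_rng(3)
        bg = rng.uniform(-1, 1, size=(500, 2))
        occ = np.tile([[0.5, -0.25]], (30, 1)) + rng.normal(0, 0.01, (30, 2))
        grid = density_grid(occ, bg, R=50)
        iy, ix = np.unravel_index(np.argmax(grid.z), grid.z.shape)
        assert grid.xs[ix] == pytest.approx(0.5, abs=0.1)
        assert grid.ys[iy] == pytest.approx(-0.25, abs=0.1)

    def test_occurrence_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(400, 2))
        occ = rng.normal(size=(50, 2)) * 0.5
        grid = density_grid(occ, bg, R=80)
        assert grid.z.sum() * grid.cell_area == pytest.approx(1.0)

    def test_matches_direct_kernel_sum_on_five_points(self):
        """Grid densities equal an explicit Gaussian kernel sum computed by
        hand with the estimator's own bandwidth matrix (5-point oracle)."""
        bg = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
        pts = np.array([[2.0, 2.0], [2.5, 2.0], [8.0, 3.0], [5.0, 7.0], [9.0, 9.0]])
        grid = density_grid(pts, bg, R=10, bandwidth_rule="silverman")
        cov_inv = np.linalg.inv(gaussian_kde(pts.T, bw_method="silverman").covariance)
        norm = np.sqrt(np.linalg.det(cov_inv)) / (2 * np.pi)
        direct = np.zeros_like(grid.z)
        for iy, gy in enumerate(grid.ys):
            for ix, gx in enumerate(grid.xs):
                d = pts - np.array([gx, gy])
                direct[iy, ix] = np.mean(norm * np.exp(-0.5 * np.einsum("ij,jk,ik->i", d, cov_inv, d)))
        direct /= direct.sum() * grid.cell_area
        assert np.allclose(grid.z, direct, atol=1e-10)

    def test_scores_outside_window_clipped_with_warning(self):
        rng = np.random.default_rng(5)
        bg = rng.uniform(0, 1, size=(200, 2))
        occ = np.vstack([rng.uniform(0, 1, size=(10, 2)), [[5.0, 5.0]]])
        with pytest.warns(UserWarning, match="clipped"):
            density_grid(occ, bg, R=20)


def indicator_grid(occupied_cells, shape=(20, 20)):
    """NicheGrid with uniform density on given cells, background everywhere."""
    z = np.zeros(shape)
    for r, c in occupied_cells:
        z[r, c] = 1.0
    z = z / z.sum()  # cell area 1
    return NicheGrid(z=z, background=np.ones(shape), xs=np.arange(shape[1], dtype=float),
                     ys=np.arange(shape[0], dtype=float))


class TestNicheDynamics:
    def test_identical_niches_give_full_stability(self):
        cells = [(i, j) for i in range(3, 8) for j in range(3, 8)]
        d = niche_dynamics(indicator_grid(cells), indicator_grid(cells),
                           occupancy_threshold=0.0)
        assert (d.stability, d.expansion, d.unfilled) == (1.0, 0.0, 0.0)

    def test_disjoint_niches_give_full_turnover(self):
        a = [(i, j) for i in range(0, 4) for j in range(0, 4)]
        b = [(i, j) for i in range(10, 14) for j in range(10, 14)]
        d = niche_dynamics(indicator_grid(a), indicator_grid(b), occupancy_threshold=0.0)
        assert (d.stability, d.expansion, d.unfilled) == (0.0, 1.0, 1.0)

    def test_constructed_overlap_matches_pixel_counting(self):
        """Reference occupies 50 cells, comparison 44, 34 shared: the indices
        are 34/50, 16/50 and 10/44 by direct cell counting."""
        ref = [(i, j) for i in range(5) for j in range(10)]  # 50 cells
        cmp_cells = ref[16:50] + [(10 + i, 10 + j) for i in range(2) for j in range(5)]
        assert len(cmp_cells) == 44
        d = niche_dynamics(indicator_grid(cmp_cells), indicator_grid(ref),
                           occupancy_threshold=0.0)
        assert d.stability == pytest.approx(0.68)
        assert d.expansion == pytest.approx(0.32)
        assert d.unfilled == pytest.approx(10 / 44)

    def test_stability_plus_expansion_is_one(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = [(int(r), int(c)) for r, c in rng.integers(0, 20, (30, 2))]
            b = [(int(r), int(c)) for r, c in rng.integers(0, 20, (30, 2))]
            d = niche_dynamics(indicator_grid(a), indicator_grid(b),
                               occupancy_threshold=0.0)
            assert d.stability + d.expansion == pytest.approx(1.0)
            assert 0 <= d.unfilled <= 1

    def test_analog_mask_excludes_one_sided_environments(self):
        # comparison background missing on the right half: occupied cells there
        # are outside the analog region and must not count
        ref = [(5, j) for j in range(4, 16)]
        bg_cmp = np.ones((20, 20))
        bg_cmp[:, 10:] = 0.0
        g_ref = indicator_grid(ref)
        g_cmp = indicator_grid(ref)
        g_cmp.background = bg_cmp
        d = niche_dynamics(g_cmp, g_ref, occupancy_threshold=0.0)
        assert d.stability == 1.0  # within the analog mask the niches coincide

    def test_empty_occupied_niche_rejected(self):
        g = indicator_grid([(1, 1)])
        empty = indicator_grid([(1, 1)])
        empty.z = np.zeros_like(empty.z)
        with pytest.raises(ValueError, match="empty occupied"):
            niche_dynamics(g, empty, occupancy_threshold=0.0)


class TestVariableOccupancy:
    def test_identical_periods_coincide_and_peak_at_one(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(10, 2, 100)
        curves = variable_occupancy(
            {"a": vals, "b": vals.copy()}, {"a": vals, "b": vals.copy()}, "MINTEMP"
        )
        assert np.allclose(curves.occupancy["a"], curves.occupancy["b"])
        for p in ("a", "b"):
            assert curves.occupancy[p].max() == pytest.approx(1.0)
            assert curves.availability[p].max() == pytest.approx(1.0)

    def test_matches_direct_kernel_sum(self):
        """Six-point oracle: density at grid nodes equals the direct Gaussian
        kernel sum with the same bandwidth."""
        vals = np.array([1.0, 2.0, 2.5, 4.0, 5.5, 6.0])
        bg = np.array([0.0, 7.0, 3.0, 4.0, 2.0, 6.0])
        curves = variable_occupancy({"p": vals}, {"p": bg}, "EVAPO", n_points=50)
        kde = gaussian_kde(vals, bw_method="silverman")
        h = np.sqrt(kde.covariance[0, 0])
        direct = np.array([
            np.mean(np.exp(-0.5 * ((x - vals) / h) ** 2) / (h * np.sqrt(2 * np.pi)))
            for x in curves.x
        ])
        assert np.allclose(curves.occupancy["p"], direct / direct.max(), atol=1e-10)

    def test_constant_values_rejected(self):
        with pytest.raises(DegenerateDensityError):
            variable_occupancy({"p": np.ones(10)}, {"p": np.random.default_rng(0).normal(size=10)},
                               "RFD")

    def test_occupied_segments_classify_overlap(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        b = rng.normal(4, 1, 200)
        bg = np.concatenate([a, b])
        curves = variable_occupancy({"a": a, "b": b}, {"a": bg, "b": bg}, "NDVI")
        seg = curves.occupied_segments(level=0.05)
        assert seg["unique_a"].any() and seg["unique_b"].any() and seg["overlap"].any()
        assert not (seg["unique_a"] & seg["unique_b"]).any()


def _period_indices(stack, presences, radius_km=400.0):
    """Outbreak vs non-outbreak dynamics indices for one occurrence set."""
    from seasonsdm.envio import extract_env

    cov = extract_env(stack, presences, VARS)
    bg = buffer_background(presences, stack, VARS, radius_km=radius_km)
    space = fit_niche_space(bg, VARS)
    bg_scores = space.transform(bg)
    out_p = cov["month"].isin([6, 7, 8, 9])
    out_b = bg["month"].isin([6, 7, 8, 9]).to_numpy()
    g_out = density_grid(space.transform(cov[out_p]), bg_scores[out_b],
                         window_scores=bg_scores)
    g_non = density_grid(space.transform(cov[~out_p]), bg_scores[~out_b],
                         window_scores=bg_scores)
    return niche_dynamics(g_out, g_non)


class TestSeasonalShift:
    def test_shifted_species_expands_and_unfills(self, study_stack, study_presences):
        """Seasonal environments make outbreak-month presences occupy partly
        new environmental space: expansion and unfilling are both positive."""
        d = _period_indices(study_stack, study_presences)
        assert d.expansion > 0 and d.unfilled > 0
        assert d.stability + d.expansion == pytest.approx(1.0)

    def test_season_constant_environment_keeps_high_stability(self, species, study_stack,
                                                              study_presences):
        """With the seasonal cycle switched off, both periods sample the same
        environment and the occupied niches coincide up to kernel-estimation
        noise at the occupied-niche boundary: stability stays high and clearly
        above the seasonal landscape's (checked over 3 seeds)."""
        from dataclasses import replace

        from seasonsdm import LandscapeConfig, generate_env_stack, sample_occurrences
        from seasonsdm.synthgrid import _default_variables

        d_shift = _period_indices(study_stack, study_presences)
        flat_vars = {
            k: replace(v, seasonal_amplitude=0.0,
                       mean=v.mean + (8 if k == "MINTEMP" else 0))
            for k, v in _default_variables().items()
        }
        for seed in range(3):
            cfg = LandscapeConfig(n_rows=40, n_cols=40, variables=flat_vars,
                                  crop_season=frozenset(range(1, 13)), seed=seed)
            stack = generate_env_stack(cfg)
            occ = sample_occurrences(species, stack, {m: 25 for m in range(1, 13)},
                                     seed=500 + seed)
            d_const = _period_indices(stack, occ)
            assert d_const.stability >= 0.8
            assert d_const.stability > d_shift.stability + 0.2
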