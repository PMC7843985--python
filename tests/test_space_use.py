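"""Projection, bandwidth, kernel UD, contours, overlap indices, null test."""

import numpy as np
import pytest

from colonyforage.space_use import (
    GridSpec,
    UtilizationDistribution,
    ba_index,
    conditional_ud,
    href_bandwidth,
    kernel_ud,
    overlap_randomization,
    project_points,
    ud_contour,
    udoi_index,
    unproject_points,
)
from colonyforage.trajectory import haversine_km

COLONY = (-63.2167, 50.1833)


def brute_force_ud(pts, h, grid):
    xs, ys = grid.centres()
    dens = np.zeros((grid.n_y, grid.n_x))
    for iy, yv in enumerate(ys):
        for ix, xv in enumerate(xs):
            dens[iy, ix] = np.exp(
                -((pts[:, 0] - xv) ** 2 + (pts[:, 1] - yv) ** 2) / (2 * h * h)
            ).sum()
    return dens / dens.sum()


def small_ud(seed=0, n=50, n_cells=40):
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 3, size=(n, 2))
    h = href_bandwidth(pts[:, 0], pts[:, 1])
    grid = GridSpec.covering(pts[:, 0], pts[:, 1], pad=3 * h, n_cells=n_cells)
    return pts, h, grid, kernel_ud(pts[:, 0], pts[:, 1], h, grid)


class TestProjection:
    def test_colony_maps_to_origin(self):
        x, y = project_points([COLONY[0]], [COLONY[1]], *COLONY)
        assert abs(x[0]) < 1e-9 and abs(y[0]) < 1e-9

    def test_point_due_north(self):
        lat10 = COLONY[1] + 10.0 / 111.19492664455873
        x, y = project_points([COLONY[0]], [lat10], *COLONY)
        assert x[0] == pytest.approx(0.0, abs=0.01)
        assert y[0] == pytest.approx(10.0, abs=0.01)

    def test_colony_distances_preserved(self):
        rng = np.random.default_rng(3)
        lon = COLONY[0] + rng.uniform(-1, 1, 50)
        lat = COLONY[1] + rng.uniform(-0.7, 0.7, 50)
        x, y = project_points(lon, lat, *COLONY)
        np.testing.assert_allclose(np.hypot(x, y), haversine_km(lon, lat, *COLONY), rtol=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-150, 150, 30)
        y = rng.uniform(-150, 150, 30)
        lon, lat = unproject_points(x, y, *COLONY)
        x2, y2 = project_points(lon, lat, *COLONY)
        np.testing.assert_allclose(x2, x, atol=1e-6)
        np.testing.assert_allclose(y2, y, atol=1e-6)


class TestHref:
    def test_formula_with_equal_marginal_sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = x.copy()  # sd_x == sd_y exactly
        sigma = x.std(ddof=1)
        assert href_bandwidth(x, y) == pytest.approx(sigma * 500 ** (-1 / 6))

    def test_million_points_unit_sd_closed_form(self):
        # h = sigma * n^(-1/6) = 0.1 for n = 1e6, sigma = 1; build a sample
        # with exact unit marginal SDs rather than allocating 1e6 draws
        base = np.array([-1.0, 1.0])
        x = np.tile(base, 500_000)
        sd = x.std(ddof=1)
        assert href_bandwidth(x / sd, x / sd) == pytest.approx(0.1, rel=1e-9)

    def test_scale_homogeneity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 200))
        assert href_bandwidth(3.7 * x, 3.7 * y) == pytest.approx(3.7 * href_bandwidth(x, y))

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            href_bandwidth(np.ones(5), np.ones(5))


class TestKernelUd:
    def test_matches_brute_force_oracle(self):
        pts, h, grid, ud = small_ud()
        np.testing.assert_allclose(ud.mass, brute_force_ud(pts, h, grid), atol=1e-12)

    def test_single_point_unimodal(self):
        grid = GridSpec(-5.0, -5.0, 0.25, 41, 41)
        ud = kernel_ud(np.array([0.3]), np.array([-0.2]), 1.0, grid)
        assert ud.mass.sum() == pytest.approx(1.0)
        iy, ix = np.unravel_index(np.argmax(ud.mass), ud.mass.shape)
        xs, ys = grid.centres()
        assert abs(xs[ix] - 0.3) <= grid.cell_size
        assert abs(ys[iy] + 0.2) <= grid.cell_size

    def test_two_distant_points_split_mass(self):
        grid = GridSpec(-20.0, -20.0, 0.5, 81, 81)
        ud = kernel_ud(np.array([-10.0, 10.0]), np.array([0.0, 0.0]), 0.5, grid)
        left = ud.mass[:, : 40].sum()
        assert left == pytest.approx(0.5, abs=1e-6)

    def test_grid_coverage_enforced(self):
        grid = GridSpec(0.0, 0.0, 1.0, 5, 5)
        with pytest.raises(ValueError):
            kernel_ud(np.array([100.0]), np.array([0.0]), 1.0, grid)


class TestContours:
    def test_nesting(self):
        _, _, _, ud = small_ud(seed=5)
        masks = [ud_contour(ud, lv) for lv in (25, 50, 75, 95)]
        for inner, outer in zip(masks, masks[1:]):
            assert (outer | inner == outer).all()

    def test_minimality(self):
        _, _, _, ud = small_ud(seed=6)
        for level in (25, 50, 75, 95):
            mask = ud_contour(ud, level)
            inside = ud.mass[mask]
            assert inside.sum() >= level / 100 - 1e-12
            assert inside.sum() - inside.min() < level / 100

    def test_high_level_covers_positive_mass_only_as_needed(self):
        _, _, _, ud = small_ud(seed=7)
        mask = ud_contour(ud, 99.9999)
        assert ud.mass[mask].sum() >= 0.999999

    def test_conditional_renormalizes(self):
        _, _, _, ud = small_ud(seed=8)
        cond = conditional_ud(ud, 50)
        assert cond.mass.sum() == pytest.approx(1.0)
        assert ((cond.mass > 0) == ud_contour(ud, 50) & (ud.mass > 0)).all()


class TestOverlapIndices:
    def test_ba_self_is_one_and_symmetric(self):
        _, _, grid, ud = small_ud(seed=9)
        rng = np.random.default_rng(10)
        pts2 = rng.normal(1, 2, size=(30, 2))
        ud2 = kernel_ud(pts2[:, 0], pts2[:, 1], 1.2, grid, check_coverage=False)
        assert ba_index(ud, ud) == pytest.approx(1.0)
        assert ba_index(ud, ud2) == pytest.approx(ba_index(ud2, ud))
        assert 0.0 <= ba_index(ud, ud2) <= 1.0

    def test_disjoint_supports_give_zero(self):
        grid = GridSpec(0.0, 0.0, 1.0, 10, 10)
        m1 = np.zeros((10, 10)); m1[:5] = 1 / 50
        m2 = np.zeros((10, 10)); m2[5:] = 1 / 50
        u1 = UtilizationDistribution("a", grid, m1, 1.0)
        u2 = UtilizationDistribution("b", grid, m2, 1.0)
        assert ba_index(u1, u2) == 0.0
        assert udoi_index(u1, u2) == 0.0

    def test_ba_uniform_nested_quarter(self):
        # ud1 uniform on A∪B (n cells), ud2 uniform on B with |B| = n/4:
        # BA = Σ_B sqrt(1/n * 4/n) = (n/4)·(2/n) = 1/2
        grid = GridSpec(0.0, 0.0, 1.0, 4, 4)
        m1 = np.full((4, 4), 1 / 16)
        m2 = np.zeros((4, 4)); m2[:1, :] = 1 / 4
        u1 = UtilizationDistribution("a", grid, m1, 1.0)
        u2 = UtilizationDistribution("b", grid, m2, 1.0)
        assert ba_index(u1, u2) == pytest.approx(0.5)

    def test_udoi_identical_uniform_is_one(self):
        grid = GridSpec(0.0, 0.0, 0.5, 20, 20)
        m = np.zeros((20, 20)); m[5:15, 5:15] = 1 / 100
        u = UtilizationDistribution("a", grid, m, 1.0)
        assert udoi_index(u, u) == pytest.approx(1.0)

    def test_udoi_exceeds_one_for_concentrated_identical_uds(self):
        _, _, _, ud = small_ud(seed=11)
        sharp = kernel_ud(np.zeros(3), np.zeros(3), 0.3, ud.grid, check_coverage=False)
        assert udoi_index(sharp, sharp) > 1.0

    def test_grid_mismatch_rejected(self):
        _, _, _, ud = small_ud(seed=12)
        other = GridSpec(0.0, 0.0, 1.0, 10, 10)
        m = np.full((10, 10), 1 / 100)
        u2 = UtilizationDistribution("b", other, m, 1.0)
        with pytest.raises(ValueError):
            ba_index(ud, u2)


class TestRandomization:
    @staticmethod
    def trips_for(name, patches, seed, n_birds=3, n_days=1):
        from colonyforage.synthetic import SimScenario, simulate_tracks
        from colonyforage.trajectory import SpeciesParams, segment_tracks

        sc = SimScenario(name, patch_centers=patches, n_birds=n_birds, n_days=n_days, seed=seed)
        fixes, _ = simulate_tracks(sc)
        params = {name: SpeciesParams(name, sc.colony_lon, sc.colony_lat,
                                      sc.splash_radius_m, 80.0, 5.0)}
        _, trips = segment_tracks(fixes, params)
        return trips

    def test_determinism_under_fixed_seed(self):
        ta = self.trips_for("spA", ((15.0, 10.0),), 1)
        tb = self.trips_for("spB", ((14.0, 11.0),), 2)
        r1 = overlap_randomization(ta, tb, COLONY, n_iter=20, seed=9, n_cells=40)
        r2 = overlap_randomization(ta, tb, COLONY, n_iter=20, seed=9, n_cells=40)
        np.testing.assert_array_equal(r1.null_ba, r2.null_ba)
        assert r1.p_ba == r2.p_ba

    def test_disjoint_fields_detected(self):
        ta = self.trips_for("spA", ((12.0, 30.0), (15.0, 28.0)), 1, n_days=2)
        tb = self.trips_for("spB", ((12.0, -30.0), (15.0, -28.0)), 2, n_days=2)
        res = overlap_randomization(ta, tb, COLONY, level=95.0, n_iter=200, seed=5, n_cells=60)
        assert res.ba == pytest.approx(0.0, abs=1e-6)
        assert res.udoi == pytest.approx(0.0, abs=1e-6)
        assert res.p_ba <= 2 / 201

    def test_requires_two_trips_per_group(self):
        ta = self.trips_for("spA", ((15.0, 10.0),), 1)
        with pytest.raises(ValueError):
            overlap_randomization(ta[:1], ta[1:], COLONY, n_iter=5, seed=0)
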