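import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from oracles import brute_force_region_labels

from lysoprof import (
    CellGeometry,
    assign_regions,
    check_convex,
    compare_profiles,
    polygon_centroid,
    radial_profile,
    ray_boundary_distance,
)
from lysoprof.simulate import CellSimParams, simulate_cell

SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


def regular_polygon(n, radius, center=(0.0, 0.0)):
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.c_[
        center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)
    ]


def random_convex_polygon(rng, n_points=20, radius=1.0, center=(0.0, 0.0)):
    pts = center + rng.uniform(-radius, radius, (n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


class TestCheckConvex:
    def test_square_is_convex(self):
        assert check_convex(SQUARE)

    def test_star_is_concave(self):
        star = [(0, 2), (0.5, 0.5), (2, 0), (0.5, -0.5), (0, -2),
                (-0.5, -0.5), (-2, 0), (-0.5, 0.5)]
        assert not check_convex(star)

    def test_random_hulls_are_convex(self, rng):
        for _ in range(20):
            assert check_convex(random_convex_polygon(rng))

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            check_convex([(0, 0), (1, 1)])


class TestCentroid:
    def test_unit_square(self):
        assert polygon_centroid(SQUARE) == pytest.approx((0.5, 0.5))

    def test_triangle_vertex_mean(self):
        assert polygon_centroid([(0, 0), (3, 0), (0, 3)]) == pytest.approx((1, 1))

    def test_matches_monte_carlo_interior_mean(self, rng):
        poly = random_convex_polygon(rng)
        shp = Polygon(poly)
        minx, miny, maxx, maxy = shp.bounds
        pts = rng.uniform((minx, miny), (maxx, maxy), (200_000, 2))
        inside = np.array([shp.contains(Point(p)) for p in pts])
        mc = pts[inside].mean(axis=0)
        assert polygon_centroid(poly) == pytest.approx(tuple(mc), abs=1e-2)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            polygon_centroid([(0, 0), (1, 1), (2, 2)])


class TestRayBoundaryDistance:
    def test_unit_square_from_center(self):
        assert ray_boundary_distance(SQUARE, (0.5, 0.5), 0.0) == pytest.approx(0.5)
        assert ray_boundary_distance(SQUARE, (0.5, 0.5), math.pi / 2) == \
            pytest.approx(0.5)

    def test_circle_limit(self):
        circle = regular_polygon(360, 1.0)
        for ang in (0.1, 1.3, 2.9, 4.4, 6.0):
            assert ray_boundary_distance(circle, (0, 0), ang) == \
                pytest.approx(1.0, abs=1e-3)

    def test_origin_outside_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            ray_boundary_distance(SQUARE, (2.0, 2.0), 0.0)

    def test_matches_bisection_oracle(self, rng):
        poly = random_convex_polygon(rng, radius=5.0)
        shp = Polygon(poly)
        origin = polygon_centroid(poly)
        for ang in rng.uniform(0, 2 * math.pi, 200):
            d = ray_boundary_distance(poly, origin, ang)
            # bisection on point-in-polygon along the ray
            lo, hi = 0.0, 20.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                p = Point(origin[0] + mid * math.cos(ang),
                          origin[1] + mid * math.sin(ang))
                if shp.contains(p):
                    lo = mid
                else:
                    hi = mid
            assert d == pytest.approx(0.5 * (lo + hi), abs=1e-6)


def concentric_geometry(nuc_r=10.0, cell_r=50.0, shape=(128, 128)):
    c = (shape[1] / 2.0, shape[0] / 2.0)
    return CellGeometry(
        regular_polygon(720, cell_r, c), regular_polygon(720, nuc_r, c), shape
    ), c


class TestAssignRegions:
    def test_concentric_circles_closed_form(self):
        geom, (cx, cy) = concentric_geometry()
        rm = assign_regions(geom, R=4)
        # f = (r - 10) / 40 on circles
        assert rm.labels[int(cy), int(cx + 15)] == 0  # f = 0.125
        assert rm.labels[int(cy), int(cx + 49)] == 3  # f = 0.975
        assert rm.labels[int(cy + 35), int(cx)] == 2  # f = 0.625
        assert rm.labels[int(cy), int(cx)] == -1  # nucleus centroid
        assert rm.labels[int(cy), int(cx + 55)] == -2  # outside cell

    def test_geometry_invariants_enforced(self):
        star = [(0, 2), (0.5, 0.5), (2, 0), (0.5, -0.5), (0, -2),
                (-0.5, -0.5), (-2, 0), (-0.5, 0.5)]
        with pytest.raises(ValueError, match="convex"):
            CellGeometry(star, regular_polygon(8, 0.2), (64, 64))
        with pytest.raises(ValueError, match="inside"):
            CellGeometry(
                regular_polygon(16, 5.0, (10, 10)),
                regular_polygon(16, 9.0, (10, 10)),
                (64, 64),
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_edge_enumeration_oracle(self, seed):
        """Vectorized labels equal the per-pixel scalar ray oracle on every
        pixel of a 64x64 random convex geometry."""
        p = CellSimParams(image_shape=(64, 64), n_puncta=0, seed=seed)
        _, geom, _ = simulate_cell(p)
        rm = assign_regions(geom, R=8)
        oracle = brute_force_region_labels(geom, 8)
        assert np.array_equal(rm.labels, oracle)

    def test_every_pixel_labeled(self):
        geom, _ = concentric_geometry()
        rm = assign_regions(geom, R=8)
        assert set(np.unique(rm.labels)) <= set(range(-2, 8))


class TestRadialProfile:
    def test_uniform_image_flat_profile(self):
        geom, _ = concentric_geometry()
        rm = assign_regions(geom, R=8)
        prof = radial_profile(np.ones(geom.image_shape), rm)
        assert (prof.region_mean_norm == 1.0).all()
        np.testing.assert_allclose(
            prof.cumulative_norm,
            np.cumsum(prof.region_area_px) / prof.region_area_px.sum(),
            atol=1e-12,
        )

    def test_all_intensity_in_innermost_shell(self):
        geom, _ = concentric_geometry()
        rm = assign_regions(geom, R=4)
        img = np.where(rm.labels == 0, 5.0, 0.0)
        prof = radial_profile(img, rm)
        np.testing.assert_allclose(prof.cumulative_norm, 1.0, atol=1e-12)

    def test_weighted_mean_identity_and_conservation(self, rng):
        p = CellSimParams(seed=9, n_puncta=200)
        img, geom, _ = simulate_cell(p)
        rm = assign_regions(geom, R=8)
        prof = radial_profile(img, rm)
        w = prof.region_area_px / prof.region_area_px.sum()
        assert (prof.region_mean_norm * w).sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.cumulative_norm[-1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(prof.cumulative_norm) >= 0).all()
        # conservation: shell sums add to total cytosolic intensity exactly
        shell_total = sum(
            img[rm.labels == r].sum() for r in range(8)
        )
        assert shell_total == img[rm.labels >= 0].sum()

    def test_rotation_invariance(self):
        p = CellSimParams(seed=5, n_puncta=150)
        img, geom, _ = simulate_cell(p)
        rm = assign_regions(geom, R=8)
        H, W = img.shape

        def rot(poly):
            return np.c_[poly[:, 1], W - 1 - poly[:, 0]]

        geom_r = CellGeometry(
            rot(geom.cell_polygon), rot(geom.nucleus_polygon), (W, H)
        )
        rm_r = assign_regions(geom_r, R=8)
        assert np.array_equal(np.rot90(rm.labels), rm_r.labels)
        prof = radial_profile(img, rm)
        prof_r = radial_profile(np.rot90(img), rm_r)
        np.testing.assert_allclose(
            prof.region_mean_norm, prof_r.region_mean_norm, atol=1e-12
        )

    def test_refinement_consistency_r8_to_r4(self):
        p = CellSimParams(seed=13, n_puncta=200)
        img, geom, _ = simulate_cell(p)
        p8 = radial_profile(img, assign_regions(geom, R=8))
        p4 = radial_profile(img, assign_regions(geom, R=4))
        agg = np.array(
            [
                (p8.region_mean_norm[2 * j: 2 * j + 2]
                 * p8.region_area_px[2 * j: 2 * j + 2]).sum()
                / p8.region_area_px[2 * j: 2 * j + 2].sum()
                for j in range(4)
            ]
        )
        np.testing.assert_allclose(agg, p4.region_mean_norm, atol=1e-9)
        np.testing.assert_allclose(
            p8.cumulative_norm[1::2], p4.cumulative_norm, atol=1e-9
        )

    def test_empty_shell_advises_lower_r(self):
        geom, _ = concentric_geometry(nuc_r=20.0, cell_r=21.2, shape=(64, 64))
        with pytest.raises(ValueError, match="lower"):
            radial_profile(
                np.ones(geom.image_shape), assign_regions(geom, R=16)
            )

    def test_zero_intensity_warns(self):
        geom, _ = concentric_geometry()
        rm = assign_regions(geom, R=4)
        with pytest.warns(RuntimeWarning):
            prof = radial_profile(np.zeros(geom.image_shape), rm)
        assert (prof.region_mean_norm == 0).all()


class TestCompareProfiles:
    @staticmethod
    def _profiles(rng, n_cells, shift=0.0):
        from lysoprof import RadialProfile

        out = []
        for _ in range(n_cells):
            mean = 1.0 + rng.normal(0, 0.05, 8)
            mean[0] += shift
            out.append(
                RadialProfile(8, mean, np.full(8, 100), np.linspace(1 / 8, 1, 8))
            )
        return out

    def test_identical_groups_all_p_one(self, rng):
        a = self._profiles(rng, 5)
        cmp_ = compare_profiles(a, list(a))
        np.testing.assert_allclose(cmp_.p_values, 1.0)
        assert cmp_.direction == ["none"] * 8

    def test_shifted_shell_detected(self, rng):
        a = self._profiles(rng, 10)
        b = self._profiles(rng, 10, shift=0.25)  # 5 sd of the noise
        cmp_ = compare_profiles(a, b)
        assert cmp_.p_values[0] < 0.001
        assert cmp_.direction[0] == "up"
        assert (cmp_.p_values[1:] > 0.05).sum() >= 6

    def test_label_swap_symmetry(self, rng):
        a = self._profiles(rng, 6)
        b = self._profiles(rng, 6, shift=0.1)
        ab = compare_profiles(a, b)
        ba = compare_profiles(b, a)
        np.testing.assert_allclose(ab.p_values, ba.p_values, atol=1e-12)

    def test_mismatched_r_is_error(self, rng):
        from lysoprof import RadialProfile

        a = self._profiles(rng, 3)
        bad = RadialProfile(4, np.ones(4), np.full(4, 10), np.linspace(0.25, 1, 4))
        with pytest.raises(ValueError, match="R"):
            compare_profiles(a, [bad, bad])
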