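"""Midline, reflection, and polygon measures against independent oracles."""

import numpy as np
import pytest
from skimage.draw import polygon as raster_polygon

from mammometry.geometry import (
    GeometryError,
    Line2D,
    Polygon2D,
    estimate_midline,
    extent_perpendicular_to,
    lowest_contour_point,
    polygon_area,
    polygon_intersection_area,
    polygon_perimeter,
    reflect,
)
from conftest import build_set, rotate_set


def random_simple_polygon(rng, n=13, center=(0.0, 0.0), rmin=20.0, rmax=60.0):
    """Star-shaped (hence simple) n-gon around a center."""
    radii = rng.uniform(rmin, rmax, n)
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    return np.column_stack([center[0] + radii * np.cos(theta),
                            center[1] + radii * np.sin(theta)])


def raster_area(vertices, scale=10.0, pad=5.0):
    """Rasterization oracle: pixel count of the filled polygon at high resolution."""
    v = np.asarray(vertices, dtype=float)
    lo = v.min(axis=0) - pad
    pts = (v - lo) * scale
    size = int(np.ceil(pts.max() + pad * scale))
    rr, cc = raster_polygon(pts[:, 1], pts[:, 0], shape=(size, size))
    return len(rr) / scale**2


def raster_intersection_area(a, b, scale=10.0, pad=5.0):
    av, bv = np.asarray(a, float), np.asarray(b, float)
    lo = np.vstack([av, bv]).min(axis=0) - pad
    size = int(np.ceil((np.vstack([av, bv]) - lo).max() * scale + pad * scale))
    masks = []
    for v in (av, bv):
        pts = (v - lo) * scale
        mask = np.zeros((size, size), dtype=bool)
        rr, cc = raster_polygon(pts[:, 1], pts[:, 0], shape=(size, size))
        mask[rr, cc] = True
        masks.append(mask)
    return (masks[0] & masks[1]).sum() / scale**2


class TestMidline:
    def test_vertical_midline(self, symmetric_set):
        line = estimate_midline(symmetric_set)
        np.testing.assert_allclose(line.direction, [0, 1])
        assert line.point[0] == 200.0

    def test_oblique_direction_normalized(self):
        lset = build_set(sn=(100.0, 50.0), um=(110.0, 450.0))
        line = estimate_midline(lset)
        np.testing.assert_allclose(line.direction, np.array([10, 400]) / np.hypot(10, 400))

    def test_rotation_equivariance(self, symmetric_set):
        line0 = estimate_midline(symmetric_set)
        rot = rotate_set(symmetric_set, 17.0)
        line1 = estimate_midline(rot)
        th = np.radians(17.0)
        expected = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) @ line0.direction
        np.testing.assert_allclose(line1.direction, expected, atol=1e-12)

    def test_coincident_points_rejected(self, symmetric_set):
        bad = build_set(sn=(200.0, 60.0), um=(200.0, 60.0))
        with pytest.raises(GeometryError, match="degenerate midline"):
            estimate_midline(bad)


class TestReflect:
    AXIS = Line2D(np.array([100.0, 0.0]), np.array([0.0, 1.0]))

    def test_across_vertical_line(self):
        np.testing.assert_allclose(reflect(np.array([90.0, 200.0]), self.AXIS), [110, 200])

    def test_point_on_axis_fixed(self):
        np.testing.assert_allclose(reflect(np.array([100.0, 33.0]), self.AXIS), [100, 33])

    def test_involution_and_isometry_random_axes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            axis = Line2D(rng.uniform(-50, 50, 2), rng.uniform(-1, 1, 2) + 1e-3)
            pts = rng.uniform(-100, 100, (15, 2))
            refl = reflect(pts, axis)
            np.testing.assert_allclose(reflect(refl, axis), pts, atol=1e-9)
            d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            d1 = np.linalg.norm(refl[:, None] - refl[None, :], axis=-1)
            np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestPolygonMeasures:
    def test_unit_square_and_triangle(self):
        sq = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        tri = Polygon2D(np.array([[0, 0], [4, 0], [0, 3]], float))
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_perimeter(sq) == pytest.approx(4.0)
        assert polygon_area(tri) == pytest.approx(6.0)
        assert polygon_perimeter(tri) == pytest.approx(12.0)

    def test_self_intersecting_rejected(self):
        with pytest.raises(GeometryError):
            Polygon2D(np.array([[0, 0], [2, 2], [2, 0], [0, 2]], float))

    def test_area_matches_rasterization_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = random_simple_polygon(rng)
            area = polygon_area(Polygon2D(v))
            assert area == pytest.approx(raster_area(v), rel=0.005)

    def test_perimeter_homogeneity(self):
        rng = np.random.default_rng(2)
        v = random_simple_polygon(rng)
        p1 = polygon_perimeter(Polygon2D(v))
        p3 = polygon_perimeter(Polygon2D(v * 3.0))
        assert p3 == pytest.approx(3.0 * p1, rel=1e-12)

    def test_scaling_and_rigid_invariance(self):
        rng = np.random.default_rng(3)
        v = random_simple_polygon(rng)
        th = 0.61
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = v @ rot.T + [17.0, -4.0]
        assert polygon_area(Polygon2D(moved)) == pytest.approx(polygon_area(Polygon2D(v)), rel=1e-9)
        assert polygon_perimeter(Polygon2D(moved)) == pytest.approx(
            polygon_perimeter(Polygon2D(v)), rel=1e-9)
        k = 2.5
        assert polygon_area(Polygon2D(v * k)) == pytest.approx(
            k**2 * polygon_area(Polygon2D(v)), rel=1e-9)


class TestIntersection:
    def test_disjoint_identical_nested(self):
        a = Polygon2D(np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float))
        far = Polygon2D(np.array([[10, 10], [12, 10], [12, 12], [10, 12]], float))
        inner = Polygon2D(np.array([[1, 0.5], [3, 0.5], [3, 1.5], [1, 1.5]], float))
        assert polygon_intersection_area(a, far) == 0.0
        assert polygon_intersection_area(a, a) == pytest.approx(polygon_area(a))
        assert polygon_intersection_area(a, inner) == pytest.approx(polygon_area(inner))

    def test_overlapping_rectangles(self):
        a = Polygon2D(np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float))
        b = Polygon2D(np.array([[2, 1], [6, 1], [6, 3], [2, 3]], float))
        assert polygon_intersection_area(a, b) == pytest.approx(2.0)

    def test_matches_rasterization_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = random_simple_polygon(rng, center=(0, 0))
            b = random_simple_polygon(rng, center=(30, 10))
            got = polygon_intersection_area(Polygon2D(a), Polygon2D(b))
            oracle = raster_intersection_area(a, b)
            assert got == pytest.approx(oracle, rel=0.005, abs=2.0)

    def test_bounded_by_min_area(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = Polygon2D(random_simple_polygon(rng))
            b = Polygon2D(random_simple_polygon(rng, center=(20, 0)))
            inter = polygon_intersection_area(a, b)
            assert inter <= min(polygon_area(a), polygon_area(b)) + 1e-9


class TestContourQueries:
    def test_lowest_point_tie_break(self):
        sq = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        np.testing.assert_allclose(lowest_contour_point(sq), [0, 1])

    def test_unique_lowest_vertex(self):
        tri = Polygon2D(np.array([[0, 0], [4, 0], [2, 5]], float))
        np.testing.assert_allclose(lowest_contour_point(tri), [2, 5])

    def test_180_rotation_maps_lowest_to_highest(self):
        rng = np.random.default_rng(6)
        v = random_simple_polygon(rng)
        low = lowest_contour_point(Polygon2D(v))
        hi_rotated = lowest_contour_point(Polygon2D(-v))
        # lowest of the 180-degree rotated polygon is minus the highest point
        up = lowest_contour_point(Polygon2D(v), direction=np.array([0.0, -1.0]))
        assert -hi_rotated[1] == pytest.approx(up[1])
        assert low[1] == pytest.approx(v[:, 1].max())

    def test_extent_perpendicular(self):
        axis = Line2D(np.array([0.0, 0.0]), np.array([0.0, 1.0]))
        sq = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert extent_perpendicular_to(sq, axis) == pytest.approx(1.0)
        th = np.pi / 4
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sq45 = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) @ rot.T)
        assert extent_perpendicular_to(sq45, axis) == pytest.approx(np.sqrt(2))

    def test_extent_translation_invariant(self):
        rng = np.random.default_rng(7)
        axis = Line2D(np.array([3.0, 1.0]), np.array([0.3, 1.0]))
        v = random_simple_polygon(rng)
        e0 = extent_perpendicular_to(Polygon2D(v), axis)
        e1 = extent_perpendicular_to(Polygon2D(v + [100.0, -40.0]), axis)
        assert e1 == pytest.approx(e0, abs=1e-9)
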