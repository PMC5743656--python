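"""Extent-of-occurrence hulls, degenerate cases and the cropping rule."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from critb.eoo import alpha_hull, compute_eoo, convex_hull
from critb.geodesy import LocalProjection, polygon_area_km2

PROJ = LocalProjection(0.0, 25.0)


def km(points):
    return PROJ.inverse(np.asarray(points, dtype=float))


def gift_wrap_area(xy):
    """O(n*h) gift-wrapping convex hull + shoelace area — independent oracle."""
    pts = np.unique(np.asarray(xy, dtype=float), axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0
                             and np.linalg.norm(pts[j] - pts[cur])
                             > np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    v = pts[hull]
    return 0.5 * abs(
        np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    )


class TestConvexHull:
    def test_triangle_is_its_own_hull(self):
        hull = convex_hull(np.array([[0, 0], [4, 0], [0, 3]]))
        assert hull.area == pytest.approx(6.0)
        assert len(hull.exterior.coords) - 1 == 3

    def test_interior_point_excluded(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [5, 5]])
        hull = convex_hull(square)
        assert len(hull.exterior.coords) - 1 == 4
        assert hull.area == pytest.approx(100.0)

    def test_collinear_input_raises(self):
        with pytest.raises(ValueError):
            convex_hull(np.array([[0, 0], [1, 1], [2, 2]]))

    def test_random_sets_match_gift_wrapping_oracle(self, rng):
        for _ in range(50):
            xy = rng.uniform(0, 100, size=(rng.integers(4, 101), 2))
            assert convex_hull(xy).area == pytest.approx(gift_wrap_area(xy), rel=5e-3)

    def test_containment_and_permutation_invariance(self, rng):
        xy = rng.uniform(0, 50, size=(40, 2))
        hull = convex_hull(xy)
        assert all(hull.buffer(1e-9).covers(Polygon([(x, y), (x, y), (x, y)]).centroid)
                   for x, y in xy)
        shuffled = xy[rng.permutation(len(xy))]
        assert convex_hull(shuffled).area == pytest.approx(hull.area, rel=5e-3)


class TestAlphaHull:
    def test_large_alpha_equals_convex_hull(self, rng):
        xy = rng.uniform(0, 80, size=(30, 2))
        big = alpha_hull(xy, alpha_km=1e4)
        # boundary slivers with unbounded circumradii limit agreement to ~0.1%
        assert big.area == pytest.approx(convex_hull(xy).area, rel=1e-3)

    def test_two_tight_clusters_give_two_parts(self, rng):
        a = rng.normal(0, 1, size=(5, 2))
        b = rng.normal(0, 1, size=(5, 2)) + [100.0, 0.0]
        parts = alpha_hull(np.vstack([a, b]), alpha_km=5.0)
        assert parts.geom_type == "MultiPolygon"
        assert len(parts.geoms) == 2

    def test_alpha_below_min_circumradius_is_empty(self):
        xy = np.array([[0, 0], [10, 0], [5, 8]])
        assert alpha_hull(xy, alpha_km=1e-3) is None

    def test_area_monotone_in_alpha_and_bounded_by_convex(self, rng):
        xy = rng.uniform(0, 200, size=(40, 2))
        convex_area = convex_hull(xy).area
        prev = 0.0
        for alpha in [5, 20, 50, 150, 500]:
            h = alpha_hull(xy, alpha)
            area = 0.0 if h is None else h.area
            assert area >= prev - 1e-9
            assert area <= convex_area + 1e-9
            prev = area


class TestComputeEoo:
    def test_fewer_than_three_unique_points_is_undefined(self):
        res = compute_eoo(km([[0, 0], [5, 5]]))
        assert res.method_used == "undefined"
        assert res.area_km2 is None and res.hull is None
        assert any("three unique" in w for w in res.warnings)

    def test_collinear_points_get_buffered_segment(self):
        # three points on one meridian spanning L degrees, buffer b degrees:
        # planar oracle area = 2*b*L + pi*b^2 (degree space), mapped to km^2
        L, b = 2.0, 0.1
        pts = np.array([[0.0, 25.0], [1.0, 25.0], [2.0, 25.0]])
        res = compute_eoo(pts, segment_buffer_deg=b)
        assert res.method_used == "segment_buffer"
        deg_area = 2 * b * L + math.pi * b * b
        km_per_deg = math.pi * 6371.0072 / 180.0  # on the central meridian
        assert res.area_km2 == pytest.approx(deg_area * km_per_deg**2, rel=1e-2)
        assert any("straight segment" in w for w in res.warnings)

    def test_planar_square_area(self):
        res = compute_eoo(km([[0, 0], [10, 0], [10, 10], [0, 10]]))
        assert res.method_used == "convex_hull"
        assert res.area_km2 == pytest.approx(100.0, rel=5e-3)

    def test_hull_contains_all_inputs(self, rng):
        pts = km(rng.uniform(0, 150, size=(25, 2)))
        res = compute_eoo(pts)
        from shapely.geometry import Point

        hull = res.hull.buffer(1e-6)
        assert all(hull.covers(Point(lon, lat)) for lat, lon in pts)

    def test_exclude_area_crops_and_warns(self):
        pts = km([[0, 0], [100, 0], [100, 100], [0, 100]])
        full = compute_eoo(pts)
        # exclusion polygon covering roughly the lower half of the square
        lower = Polygon([(24.0, -1.0), (27.0, -1.0), (27.0, 0.45), (24.0, 0.45)])
        cropped = compute_eoo(pts, exclude_area=[lower])
        assert cropped.area_km2 < full.area_km2
        assert any("discouraged" in w for w in cropped.warnings)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            compute_eoo(np.empty((0, 2)))
        with pytest.raises(ValueError):
            compute_eoo(km([[0, 0], [1, 1], [2, 0]]), method="alpha_hull", alpha_km=-1)
        with pytest.raises(ValueError):
            compute_eoo(km([[0, 0], [1, 1], [2, 0]]), method="fancy_hull")

    def test_alpha_method_sums_disjoint_parts_with_warning(self, rng):
        a = rng.normal(0, 1, size=(6, 2))
        b = rng.normal(0, 1, size=(6, 2)) + [200.0, 0.0]
        res = compute_eoo(km(np.vstack([a, b])), method="alpha_hull", alpha_km=10.0)
        assert res.method_used == "alpha_hull"
        assert any("disjoint" in w for w in res.warnings)
        assert res.area_km2 > 0
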