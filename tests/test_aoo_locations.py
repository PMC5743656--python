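"""Grid occupancy, origin minimisation, AOO, sliding scale and PA methods."""

import numpy as np
import pytest
from shapely.geometry import box

from critb.aoo_locations import (
    compute_aoo,
    count_locations,
    minimized_cell_count,
    occupied_cells,
    sliding_cell_size_km,
)
from critb.geodesy import LocalProjection
from critb.occ_io import ProtectedAreaSet

PROJ = LocalProjection(0.0, 25.0)


def km(points):
    return PROJ.inverse(np.asarray(points, dtype=float))


def bucket_oracle(xy, side, offset):
    """Independent dictionary-bucketing cell counter."""
    buckets = set()
    for x, y in np.atleast_2d(xy):
        buckets.add((int(np.floor((x - offset[0]) / side)),
                     int(np.floor((y - offset[1]) / side))))
    return len(buckets)


def exhaustive_min_oracle(xy, side, step=0.01):
    """Global minimum cell count over a fine offset lattice."""
    best = None
    offs = np.arange(0.0, side, step)
    for dx in offs:
        for dy in offs:
            n = bucket_oracle(xy, side, (dx, dy))
            best = n if best is None else min(best, n)
    return best


class TestOccupiedCells:
    def test_single_point_one_cell(self):
        assert len(occupied_cells([[3.7, -2.1]], 2.0, (0.3, 0.9))) == 1

    def test_boundary_point_half_open_convention(self):
        # a point exactly on a boundary belongs to the larger-index cell
        cells = occupied_cells([[2.0, 0.5], [0.0, 0.5]], 2.0, (0.0, 0.0))
        assert cells == {(1, 0), (0, 0)}

    def test_matches_bucket_oracle_on_random_points(self, rng):
        for _ in range(30):
            xy = rng.uniform(-50, 50, size=(10, 2))
            off = tuple(rng.uniform(0, 3, 2))
            assert len(occupied_cells(xy, 3.0, off)) == bucket_oracle(xy, 3.0, off)

    def test_invalid_cell_side(self):
        with pytest.raises(ValueError):
            occupied_cells([[0, 0]], 0.0)


class TestMinimizedCellCount:
    def test_two_close_points_merge_into_one_cell(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        n, off = minimized_cell_count(xy, 2.0, origin_shifts=4)
        assert n == 1
        assert exhaustive_min_oracle(xy, 2.0) == 1

    def test_points_beyond_cell_diagonal_never_share(self, rng):
        xy = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0], [20.0, 20.0]])
        n, _ = minimized_cell_count(xy, 10.0, origin_shifts=5)
        assert n == 4  # pairwise farther than the cell diagonal

    def test_minimization_never_exceeds_zero_offset_count(self, rng):
        for _ in range(20):
            xy = rng.uniform(0, 30, size=(8, 2))
            n, _ = minimized_cell_count(xy, 5.0, origin_shifts=4)
            assert n <= len(occupied_cells(xy, 5.0, (0.0, 0.0)))

    def test_equals_exhaustive_lattice_when_scanned_at_same_resolution(self, rng):
        """With origin_shifts matching the 0.01-km lattice, the implementation
        agrees with the independent exhaustive-search oracle."""
        side = 1.0
        for _ in range(5):
            xy = rng.uniform(0, 3, size=(6, 2))
            n, _ = minimized_cell_count(xy, side, origin_shifts=100)
            assert n == exhaustive_min_oracle(xy, side, step=0.01)

    def test_deterministic_tie_break_row_major(self):
        xy = np.array([[100.0, 100.0]])  # every offset gives 1 cell
        _, off = minimized_cell_count(xy, 2.0, origin_shifts=4)
        assert off == (0.0, 0.0)

    def test_cell_side_doubling_never_increases_count(self, rng):
        for _ in range(20):
            xy = rng.uniform(0, 100, size=(12, 2))
            n1, _ = minimized_cell_count(xy, 5.0, 4)
            n2, _ = minimized_cell_count(xy, 10.0, 4)
            assert n2 <= n1


class TestComputeAoo:
    def test_single_occurrence_default_cells_is_4_km2(self):
        res = compute_aoo(km([[12.0, 34.0]]))
        assert res.n_cells == 1
        assert res.area_km2 == pytest.approx(4.0)

    def test_three_points_in_one_cell(self):
        # all points within 0.5 km of each other fit one 2-km cell
        res = compute_aoo(km([[0.0, 0.0], [0.4, 0.1], [0.2, 0.4]]))
        assert res.n_cells == 1
        assert res.area_km2 == pytest.approx(4.0)

    def test_area_bounded_by_point_count(self, rng):
        pts = km(rng.uniform(0, 200, size=(15, 2)))
        res = compute_aoo(pts)
        assert res.area_km2 <= 15 * 4.0
        assert 1 <= res.n_cells <= 15

    def test_empty_points_raise(self):
        with pytest.raises(ValueError):
            compute_aoo(np.empty((0, 2)))


class TestSlidingCellSize:
    def test_five_percent_of_100_km_is_5_km(self):
        pts = km([[0.0, 0.0], [100.0, 0.0]])
        side, warns = sliding_cell_size_km(pts, fraction=0.05)
        assert side == pytest.approx(5.0, rel=1e-3)
        assert warns == []

    def test_single_point_falls_back_with_warning(self):
        side, warns = sliding_cell_size_km(km([[0.0, 0.0]]), fallback_km=10.0)
        assert side == 10.0
        assert warns

    def test_linearity_in_distance(self):
        s1, _ = sliding_cell_size_km(km([[0, 0], [50, 0]]), 0.05)
        s2, _ = sliding_cell_size_km(km([[0, 0], [100, 0]]), 0.05)
        assert s2 == pytest.approx(2 * s1, rel=1e-3)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            sliding_cell_size_km(km([[0, 0], [1, 1]]), fraction=1.5)


def pa_set(*rects_km):
    """ProtectedAreaSet from planar-km (x0, y0, x1, y1) rectangles."""
    return ProtectedAreaSet(
        [(f"pa{i}", PROJ.inverse_geom(box(*r))) for i, r in enumerate(rects_km)]
    )


class TestCountLocations:
    def test_no_pa_three_distant_points(self):
        pts = km([[0, 0], [50, 0], [0, 50]])
        res = count_locations(pts, cell_side_km=10.0)
        assert res.n_locations == 3
        assert res.pa_method == "none"

    def test_all_points_in_one_pa_no_more_than_one(self):
        # widely spread points, all inside one large PA -> exactly 1 location
        pts = km([[5, 5], [80, 10], [40, 90], [70, 70], [10, 60]])
        pas = pa_set((0, 0, 100, 100))
        res = count_locations(pts, cell_side_km=10.0,
                              pa_method="no_more_than_one", pas=pas)
        assert res.n_locations == 1
        assert res.n_in_pa == 1 and res.n_outside_pa == 0

    def test_pa_boundary_splits_close_pair_under_other(self):
        # two points 4 km apart (< 10-km cell), one inside a PA, one outside
        pts = km([[48.0, 0.0], [52.0, 0.0]])
        pas = pa_set((0, -10, 50, 10))  # covers x in [0, 50]: first point only
        res = count_locations(pts, cell_side_km=10.0, pa_method="other", pas=pas)
        assert res.n_locations == 2
        assert res.n_in_pa == 1 and res.n_outside_pa == 1

    def test_two_disjoint_pas_count_separately(self):
        pts = km([[5, 5], [5, 6], [95, 95], [96, 95]])
        pas = pa_set((0, 0, 10, 10), (90, 90, 100, 100))
        res = count_locations(pts, cell_side_km=10.0,
                              pa_method="no_more_than_one", pas=pas)
        assert res.n_locations == 2
        assert set(res.pa_occupancy) == {"pa0", "pa1"}

    def test_method_ordering_bound(self, rng):
        """no_more_than_one <= other <= no-PA count + occupied PAs."""
        for _ in range(10):
            pts = km(rng.uniform(0, 150, size=(12, 2)))
            pas = pa_set((0, 0, 60, 60), (90, 90, 150, 150))
            n_none = count_locations(pts, 10.0).n_locations
            res1 = count_locations(pts, 10.0, pa_method="no_more_than_one", pas=pas)
            res2 = count_locations(pts, 10.0, pa_method="other", pas=pas)
            assert res1.n_locations <= res2.n_locations
            assert res2.n_locations <= n_none + len(res2.pa_occupancy)

    def test_partition_of_points_across_boundary(self, rng):
        pts = km(rng.uniform(0, 100, size=(20, 2)))
        pas = pa_set((0, 0, 50, 100))
        res = count_locations(pts, 10.0, pa_method="other", pas=pas)
        n_inside = sum(res.pa_occupancy.values())
        # every unique point is either inside or outside, never both/neither
        assert res.n_in_pa <= n_inside
        assert res.n_outside_pa <= 20 - n_inside

    def test_missing_pa_set_raises(self):
        with pytest.raises(ValueError):
            count_locations(km([[0, 0]]), pa_method="other", pas=None)
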