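"""Voronoi tessellation, boundary exclusion, g1, CC — against independent oracles."""

import numpy as np
import pytest

from conemosaic import (
    DegenerateGeometryError,
    InsufficientInteriorCellsError,
    InsufficientPointsError,
    PointField,
    ZeroVarianceError,
    analyze_field,
    coefficient_of_clustering,
    compute_voronoi,
    density,
    interior_mask,
    skewness_g1,
)
from conftest import random_field

from _oracle import (
    clustering_coefficient,
    halfplane_adjacency,
    halfplane_areas,
    halfplane_boundary_touch,
    raster_adjacency,
    raster_areas,
    raster_assign,
    skewness_oracle,
)


class TestComputeVoronoi:
    def test_bisectors_quarter_square(self):
        # 2x2 grid: perpendicular bisectors x=500 and y=500 cut four 250k quadrants
        field = PointField(
            np.array([[250.0, 250.0], [750.0, 250.0], [250.0, 750.0], [750.0, 750.0]]),
            (0, 0, 1000, 1000),
        )
        vr = compute_voronoi(field)
        np.testing.assert_allclose(vr.areas, 250_000.0, rtol=1e-9)
        # left half of the window belongs to the two left points
        assert vr.areas[0] + vr.areas[2] == pytest.approx(500_000, rel=1e-9)

    def test_center_cell_of_3x3_grid(self, grid_3x3_field):
        vr = compute_voronoi(grid_3x3_field)
        assert vr.areas[4] == pytest.approx(250.0**2, rel=1e-9)
        # corner cells are 375x375 by the bisector construction
        assert vr.areas[0] == pytest.approx(375.0**2, rel=1e-9)

    def test_3x3_grid_matches_raster_oracle(self, grid_3x3_field):
        vr = compute_voronoi(grid_3x3_field)
        labels = raster_assign(grid_3x3_field.points, grid_3x3_field.window, 1.0)
        oracle = raster_areas(labels, 9, 1.0)
        np.testing.assert_allclose(vr.areas, oracle, rtol=5e-3)

    def test_partition_on_random_fields(self):
        for seed in range(10):
            f = random_field(seed)
            vr = compute_voronoi(f)
            assert vr.areas.sum() == pytest.approx(f.window_area_um2, rel=1e-6)
            assert (vr.areas > 0).all()

    def test_adjacency_symmetric_irreflexive(self):
        f = random_field(3, n=100)
        vr = compute_voronoi(f)
        for i, nb in enumerate(vr.neighbors):
            assert i not in nb
            for j in nb:
                assert i in vr.neighbors[j]

    def test_interior_cells_have_three_plus_neighbors(self):
        f = random_field(4, n=150)
        vr = compute_voronoi(f)
        for i in np.flatnonzero(vr.interior):
            assert len(vr.neighbors[i]) >= 3

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            compute_voronoi(PointField(np.array([[1.0, 1], [2, 2], [3, 1]]), (0, 0, 10, 10)))

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.linspace(1, 9, 6), np.linspace(1, 9, 6)])
        with pytest.raises(DegenerateGeometryError):
            compute_voronoi(PointField(pts, (0, 0, 10, 10)))


class TestInteriorMask:
    def test_ring_around_center_leaves_center(self, hexagon_center_field):
        # tighten window so every hexagon cell touches the border
        field = hexagon_center_field.with_window((10, 10, 90, 90))
        vr = compute_voronoi(field)
        mask = interior_mask(vr, field, "window_touch")
        assert mask[0]
        assert not mask[1:].any()

    def test_10x10_grid_interior_is_inner_8x8(self, grid_10x10_field):
        vr = compute_voronoi(grid_10x10_field)
        mask = interior_mask(vr, grid_10x10_field, "window_touch")
        assert mask.sum() == 64
        idx = np.flatnonzero(mask)
        rows, cols = idx // 10, idx % 10
        assert rows.min() == 1 and rows.max() == 8
        assert cols.min() == 1 and cols.max() == 8

    def test_hull_peel_drops_hull_vertices(self):
        f = random_field(7, n=50)
        vr = compute_voronoi(f)
        from scipy.spatial import ConvexHull

        mask = interior_mask(vr, f, "hull_peel")
        hull = set(ConvexHull(f.points).vertices.tolist())
        assert set(np.flatnonzero(~mask).tolist()) == hull

    def test_all_boundary_raises_downstream(self):
        # points on one circle in a tight window: nothing interior
        ang = np.linspace(0, 2 * np.pi, 13)[:-1]
        pts = np.column_stack([50 + 45 * np.cos(ang), 50 + 45 * np.sin(ang)])
        field = PointField(pts, (0, 0, 100, 100))
        with pytest.raises(InsufficientInteriorCellsError):
            analyze_field(field)

    def test_window_touch_matches_halfplane_oracle(self):
        for seed in (0, 1, 2):
            f = random_field(seed, n=40, window=(0, 0, 200, 200))
            vr = compute_voronoi(f)
            np.testing.assert_array_equal(
                vr.boundary_touch, halfplane_boundary_touch(f.points, f.window)
            )


class TestDensity:
    def test_counts_per_mm2(self, square_window, rng):
        pts = rng.uniform(0, 1000, (100, 2))
        assert density(PointField(pts, square_window)) == pytest.approx(100.0)

    def test_smaller_window_scales(self, rng):
        pts = rng.uniform(0, 500, (100, 2))
        assert density(PointField(pts, (0, 0, 500, 500))) == pytest.approx(400.0)


class TestSkewnessG1:
    def test_symmetric_sample_is_zero(self):
        assert skewness_g1([1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-15)

    def test_printed_formula_value(self):
        # {1,1,4}: m3 = 2, m2 = 2 -> g1 = 2 / 2^1.5
        assert skewness_g1([1.0, 1.0, 4.0]) == pytest.approx(2 / 2**1.5, rel=1e-12)

    def test_reflection_negates(self, rng):
        x = rng.gamma(2.0, 3.0, size=100)
        mirrored = 2 * x.mean() - x
        assert skewness_g1(mirrored) == pytest.approx(-skewness_g1(x), rel=1e-9)

    def test_matches_scipy_biased_skew(self, rng):
        x = rng.lognormal(size=500)
        assert skewness_g1(x) == pytest.approx(skewness_oracle(x), rel=1e-12)

    def test_constant_sample_undefined(self):
        with pytest.raises(ZeroVarianceError):
            skewness_g1([5.0, 5.0, 5.0])

    def test_too_few_values(self):
        with pytest.raises(InsufficientPointsError):
            skewness_g1([1.0, 2.0])


class TestCoefficientOfClustering:
    def test_hexagon_center_matches_halfplane_oracle(self, hexagon_center_field):
        f = hexagon_center_field
        vr = compute_voronoi(f)
        vr.interior = np.ones(f.n, dtype=bool)  # tiny fixture: keep all cells
        cc = coefficient_of_clustering(vr, min_cells=2)
        oracle = clustering_coefficient(
            halfplane_areas(f.points, f.window), halfplane_adjacency(f.points, f.window)
        )
        assert cc == pytest.approx(oracle, rel=1e-9)

    def test_adjacency_matches_halfplane_oracle(self):
        for seed in range(5):
            f = random_field(seed, n=12, window=(0, 0, 120, 120))
            vr = compute_voronoi(f)
            oracle = halfplane_adjacency(f.points, f.window)
            assert [set(nb.tolist()) for nb in vr.neighbors] == oracle

    def test_constant_areas_undefined(self, grid_10x10_field):
        # interior 8x8 block of a perfect grid: every retained area is 100x100
        vr = compute_voronoi(grid_10x10_field)
        interior_mask(vr, grid_10x10_field, "window_touch")
        with pytest.raises(ZeroVarianceError):
            coefficient_of_clustering(vr)

    def test_min_cells_guard(self, hexagon_center_field):
        vr = compute_voronoi(hexagon_center_field)
        with pytest.raises(InsufficientInteriorCellsError):
            coefficient_of_clustering(vr)  # one interior cell < 10

    def test_sd_convention_changes_value(self, small_ring_field):
        vr = compute_voronoi(small_ring_field)
        interior_mask(vr, small_ring_field, "window_touch")
        cc_s = coefficient_of_clustering(vr, sd_convention="sample")
        cc_p = coefficient_of_clustering(vr, sd_convention="population")
        assert cc_s != cc_p
        assert cc_s > 0 and cc_p > 0


class TestAnalyzeField:
    def test_deterministic(self, small_homog_field):
        a = analyze_field(small_homog_field)
        b = analyze_field(small_homog_field)
        assert a.cc == b.cc
        assert a.skewness_g1 == b.skewness_g1
        np.testing.assert_array_equal(a.areas_interior, b.areas_interior)

    def test_counts_consistent(self, small_ring_field):
        st = analyze_field(small_ring_field)
        assert st.n_total == small_ring_field.n
        assert 0 < st.n_interior <= st.n_total
        assert len(st.areas_interior) == st.n_interior
        assert st.density == pytest.approx(density(small_ring_field))
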