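import math

import numpy as np
import pytest
from _oracles import exhaustive_least_cost, flood_fill_components

from pondscape import (
    GridRaster,
    HsiSurface,
    ResistanceSurface,
    binarization_threshold,
    build_graph,
    extract_patches,
    least_cost_distance,
    resistance_surface,
)


def _hsi(vals, cell=50.0):
    vals = np.asarray(vals, dtype=float)
    return HsiSurface(GridRaster(vals, origin=(0, vals.shape[0] * cell), cell_size=cell))


class TestBinarizationThreshold:
    def test_constant_presence_hsi_gives_that_constant(self):
        hsi = _hsi(np.full((4, 4), 0.37))
        pts = np.array([[25.0, 25.0], [75.0, 75.0]])
        assert binarization_threshold(hsi, pts) == pytest.approx(0.37)

    def test_linear_interpolation_percentile(self):
        vals = np.arange(0.1, 1.05, 0.1).reshape(2, 5)  # 0.1 .. 1.0
        hsi = _hsi(vals)
        pts = np.array([hsi.raster.cell_center(r, c) for r in range(2) for c in range(5)])
        assert binarization_threshold(hsi, pts) == pytest.approx(0.19)
        assert binarization_threshold(hsi, pts) <= vals.max()

    def test_no_valid_presence_rejected(self):
        hsi = _hsi(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            binarization_threshold(hsi, np.array([[25.0, 25.0]]))


class TestExtractPatches:
    def test_corner_touching_cells_join_one_patch(self):
        vals = np.zeros((3, 3))
        vals[0, 0] = vals[1, 1] = 0.8
        patches = extract_patches(_hsi(vals), 0.5)
        assert len(patches) == 1
        assert patches[0].area == 2 * 2500.0

    def test_capacity_is_mean_hsi(self):
        vals = np.zeros((3, 3))
        vals[0, :2] = [0.6, 0.8]
        (p,) = extract_patches(_hsi(vals), 0.5)
        assert p.capacity == pytest.approx(0.7)

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(size=(20, 20))
            patches = extract_patches(_hsi(vals), 0.7)
            assert len(patches) == flood_fill_components(vals >= 0.7)

    def test_partition_is_disjoint_and_covers_suitable_cells(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(15, 15))
        patches = extract_patches(_hsi(vals), 0.6)
        all_cells = np.vstack([p.cells for p in patches]) if patches else np.empty((0, 2))
        assert len(all_cells) == len(set(map(tuple, all_cells)))
        assert len(all_cells) == int(np.sum(vals >= 0.6))
        # deterministic row-major id order
        firsts = [tuple(p.cells[np.lexsort((p.cells[:, 1], p.cells[:, 0]))][0]) for p in patches]
        assert firsts == sorted(firsts)


class TestResistanceSurface:
    def test_printed_formula_endpoints_and_midpoint(self):
        hsi = _hsi([[0.0, 0.2, 0.4, 1.0]])
        res = resistance_surface(hsi, 0.4).raster.values
        assert res[0, 0] == pytest.approx(1000.0)
        assert res[0, 1] == pytest.approx(1000.0 * math.sqrt(0.001))  # HSI = threshold/2
        assert res[0, 2] == 1.0
        assert res[0, 3] == 1.0

    def test_continuous_at_threshold_and_monotone(self):
        thr = 0.35
        h = np.linspace(0, 1, 2001)
        res = resistance_surface(_hsi(h[None, :]), thr).raster.values[0]
        just_below = resistance_surface(_hsi([[thr - 1e-12]]), thr).raster.values[0, 0]
        assert abs(just_below - 1.0) < 1e-9  # continuous at the threshold
        assert np.all(np.diff(res) <= 1e-12)  # non-increasing in HSI
        assert res.min() >= 1.0 and res.max() <= 1000.0
        with pytest.raises(ValueError):
            resistance_surface(_hsi(h[None, :]), 0.0)


class TestLeastCostDistance:
    def test_unit_resistance_straight_line(self):
        vals = np.ones((1, 11))
        res = ResistanceSurface(GridRaster(vals, origin=(0, 50), cell_size=50.0))
        d = least_cost_distance(res, np.array([[0, 0]]), np.array([[0, 10]]))
        assert d == pytest.approx(500.0)

    def test_matches_exhaustive_enumeration_on_small_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            shape = (rng.integers(2, 5), rng.integers(2, 5))
            vals = np.exp(rng.uniform(0, math.log(1000), size=shape))
            res = ResistanceSurface(GridRaster(vals, cell_size=50.0))
            start = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
            goal = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
            if start == goal:
                continue
            got = least_cost_distance(res, np.array([start]), np.array([goal]))
            want = exhaustive_least_cost(vals, 50.0, start, goal)
            assert got == pytest.approx(want, rel=1e-9)

    def test_cost_distance_dominates_euclidean(self):
        rng = np.random.default_rng(7)
        vals = 1.0 + 999.0 * rng.uniform(size=(8, 8))
        ras = GridRaster(vals, origin=(0, 400), cell_size=50.0)
        res = ResistanceSurface(ras)
        d = least_cost_distance(res, np.array([[0, 0]]), np.array([[7, 7]]))
        eucl = math.hypot(*(np.subtract(ras.cell_center(0, 0), ras.cell_center(7, 7))))
        assert d >= eucl


class TestBuildGraph:
    def test_single_patch_graph(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 0.9
        g = build_graph(_hsi(vals), None, threshold=0.5)
        assert len(g.patches) == 1 and len(g.edges) == 0
        assert not g.is_empty

    def test_zero_patches_is_an_empty_graph_not_an_error(self):
        g = build_graph(_hsi(np.zeros((4, 4))), None, threshold=0.5)
        assert g.is_empty and g.edges == {}

    def test_pairs_beyond_dispersal_distance_are_pruned(self):
        vals = np.full((1, 41), 0.9)
        vals[0, 1:40] = 0.449  # moderately hostile corridor
        hsi = _hsi(vals)
        g = build_graph(hsi, None, threshold=0.45, dispersal_dist=1000.0)
        assert len(g.patches) == 2
        assert len(g.edges) == 0  # 39 moves x 50 m x elevated resistance > 1 km

    def test_unit_terrain_edge_costs_equal_straight_line_distances(self):
        # three 1-cell patches over a hand-built unit resistance surface
        res = ResistanceSurface(GridRaster(np.ones((9, 9)), origin=(0, 450), cell_size=50.0))
        a, b, c = np.array([[0, 0]]), np.array([[0, 8]]), np.array([[8, 0]])
        assert least_cost_distance(res, a, b) == pytest.approx(8 * 50.0)
        assert least_cost_distance(res, a, c) == pytest.approx(8 * 50.0)
        assert least_cost_distance(res, b, c) == pytest.approx(8 * math.sqrt(2) * 50.0)

    def test_edge_costs_through_uniform_matrix_match_hand_computation(self):
        vals = np.full((9, 9), 0.9)
        vals[0, 0] = vals[0, 8] = vals[8, 0] = 0.95
        hsi = _hsi(vals, cell=50.0)
        g = build_graph(hsi, None, threshold=0.93, dispersal_dist=10000.0)
        assert len(g.patches) == 3
        r = math.exp(math.log(0.001) * 0.9 / 0.93) * 1000.0  # matrix resistance
        straight = 50.0 * (1.0 + r) / 2 * 2 + 6 * 50.0 * r  # 2 boundary + 6 interior moves
        assert g.edges[(0, 1)] == pytest.approx(straight)
        assert g.edges[(0, 2)] == pytest.approx(straight)
        assert g.edges[(1, 2)] == pytest.approx(straight * math.sqrt(2))

    def test_alpha_calibration_at_dispersal_distance(self):
        vals = np.zeros((3, 3))
        vals[0, 0] = 0.9
        g = build_graph(_hsi(vals), None, threshold=0.5, dispersal_dist=2000.0)
        assert math.exp(-g.alpha * 2000.0) == pytest.approx(0.05)

    def test_triangle_inequality_with_patch_diameter_slack(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.3, 1.0, size=(12, 12))
        hsi = _hsi(vals)
        g = build_graph(hsi, None, threshold=0.8, dispersal_dist=1e9)
        dist = {k: v for k, v in g.edges.items()}

        def d(i, j):
            return dist.get((min(i, j), max(i, j)), np.inf)

        cell = hsi.raster.cell_size
        for j, pj in enumerate(g.patches):
            diam = math.hypot(*np.ptp(pj.cells, axis=0)) * cell + 2 * cell
            for i in range(len(g.patches)):
                for k in range(len(g.patches)):
                    if len({i, j, k}) < 3:
                        continue
                    if np.isfinite(d(i, j)) and np.isfinite(d(j, k)):
                        assert d(i, k) <= d(i, j) + d(j, k) + diam * math.sqrt(2) + 1e-6
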