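"""Q4 core extraction, resistance mapping, least-cost corridors."""

import itertools
import math

import numpy as np
import pytest

from straitpop.connectivity import (
    CorePatch,
    HQIGrid,
    core_areas,
    core_threshold,
    corridor_network,
    least_cost_paths,
    read_ascii_grid,
    resistance_surface,
    write_ascii_grid,
)
from straitpop.errors import EmptyGridError
from straitpop.synthetic import simulate_hqi_grid

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def patch(pid, cells):
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    return CorePatch(pid, list(cells), len(cells),
                     (sum(rows) / len(rows), sum(cols) / len(cols)))


def brute_force_min_cost(resistance, source, target, cell_size=1.0):
    """Exhaustive DFS over simple paths with exact cost-bound pruning."""
    n_rows, n_cols = resistance.shape
    best = [math.inf]

    def dfs(r, c, cost, visited):
        if cost >= best[0]:
            return  # pruning at an exact bound keeps the search exhaustive
        if (r, c) == target:
            best[0] = cost
            return
        for dr, dc in _EIGHT:
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and (nr, nc) not in visited:
                rr = resistance[nr, nc]
                if not math.isfinite(rr):
                    continue
                step = cell_size * math.sqrt(2) if dr and dc else cell_size
                dfs(nr, nc, cost + step * (resistance[r, c] + rr) / 2.0, visited | {(nr, nc)})

    dfs(*source, 0.0, {source})
    return best[0]


class TestCoreAreas:
    def test_sixteen_cell_ramp_has_four_core_cells_in_one_patch(self):
        values = (np.arange(1, 17, dtype=float).reshape(4, 4) - 1) / 15.0
        grid = HQIGrid(values=values)
        # 75th percentile of 1..16 (linear interpolation) is 12.25, i.e. the
        # rescaled threshold (12.25-1)/15; cells 13..16 qualify
        assert core_threshold(grid) == pytest.approx((12.25 - 1) / 15.0)
        patches = core_areas(grid)
        assert len(patches) == 1
        assert patches[0].area_cells == 4
        assert sorted(patches[0].cells) == [(3, 0), (3, 1), (3, 2), (3, 3)]

    def test_constant_grid_is_one_all_core_patch(self):
        grid = HQIGrid(values=np.full((3, 5), 0.4))
        patches = core_areas(grid)
        assert len(patches) == 1 and patches[0].area_cells == 15

    def test_diagonal_adjacency_joins_but_nodata_gap_splits(self):
        nan = np.nan
        touching = HQIGrid(values=np.array([[1.0, nan], [nan, 1.0]]))
        assert len(core_areas(touching)) == 1
        gapped = HQIGrid(values=np.array(
            [[1.0, nan, nan], [nan, nan, nan], [nan, nan, 1.0]]
        ))
        assert len(core_areas(gapped)) == 2

    def test_all_nodata_grid_is_rejected(self):
        with pytest.raises(EmptyGridError):
            core_areas(HQIGrid(values=np.full((3, 3), np.nan)))

    def test_core_cell_count_shrinks_as_threshold_rises(self):
        grid = simulate_hqi_grid(20, 20, n_bumps=3, bump_width=2.0, seed=5)
        counts = [
            sum(p.area_cells for p in core_areas(grid, quantile=q))
            for q in (0.5, 0.65, 0.75, 0.85, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)


class TestResistance:
    @pytest.mark.parametrize("hqi,want", [(1.0, 1.0), (0.0, 100.0), (0.5, 50.5)])
    def test_linear_inversion_endpoints(self, hqi, want):
        grid = HQIGrid(values=np.array([[hqi]]))
        assert resistance_surface(grid)[0, 0] == want

    def test_nodata_cells_are_impassable(self):
        grid = HQIGrid(values=np.array([[0.5, np.nan]]))
        assert math.isinf(resistance_surface(grid)[0, 1])


class TestLeastCost:
    def test_three_cell_line_hand_evaluation(self):
        resistance = np.array([[1.0, 2.0, 3.0]])
        corridors = least_cost_paths(
            resistance, [patch(1, [(0, 0)]), patch(2, [(0, 2)])], cell_size=1.0
        )
        assert corridors[0].cost == pytest.approx(4.0)  # 1.5 + 2.5
        assert corridors[0].path == [(0, 0), (0, 1), (0, 2)]

    def test_cost_within_a_single_patch_is_zero(self):
        resistance = np.full((3, 3), 5.0)
        cells = [(0, 0), (0, 1)]
        corridors = least_cost_paths(
            resistance, [patch(1, cells), patch(2, [(0, 1)])], cell_size=1.0
        )
        # target patch overlaps a source cell: nothing to traverse
        assert corridors[0].cost == 0.0

    def test_unreachable_pair_is_flagged_not_dropped(self):
        resistance = np.array([[1.0, np.inf, 1.0]])
        corridors = least_cost_paths(
            resistance, [patch(1, [(0, 0)]), patch(2, [(0, 2)])], cell_size=1.0
        )
        assert len(corridors) == 1
        assert math.isinf(corridors[0].cost) and not corridors[0].reachable
        assert corridors[0].path is None

    @pytest.mark.parametrize("seed", range(100))
    def test_dijkstra_equals_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        resistance = rng.uniform(1.0, 100.0, size=(5, 5))
        source, target = (0, 0), (4, 4)
        got = least_cost_paths(
            resistance, [patch(1, [source]), patch(2, [target])], cell_size=1.0
        )[0].cost
        want = brute_force_min_cost(resistance, source, target)
        assert got == pytest.approx(want, rel=1e-12)

    def test_cost_scales_linearly_with_resistance(self):
        rng = np.random.default_rng(7)
        resistance = rng.uniform(1.0, 50.0, size=(6, 6))
        cores = [patch(1, [(0, 0)]), patch(2, [(5, 5)])]
        base = least_cost_paths(resistance, cores)[0].cost
        scaled = least_cost_paths(3.0 * resistance, cores)[0].cost
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_cost_is_symmetric_under_endpoint_swap(self):
        rng = np.random.default_rng(9)
        resistance = rng.uniform(1.0, 100.0, size=(6, 6))
        a, b = patch(1, [(0, 1), (1, 0)]), patch(2, [(5, 4), (4, 5)])
        forward = least_cost_paths(resistance, [a, b])[0].cost
        backward = least_cost_paths(resistance, [
            patch(1, b.cells), patch(2, a.cells)
        ])[0].cost
        assert forward == pytest.approx(backward, rel=1e-12)


class TestNetwork:
    def test_two_bump_raster_gives_two_cores_one_linkage(self):
        grid = simulate_hqi_grid(30, 30, n_bumps=2, bump_width=2.5, seed=11)
        net = corridor_network(grid)
        assert net.summary["n_cores"] == 2
        assert net.summary["n_linkages"] == 1
        assert net.corridors[0].reachable

    def test_single_bump_has_no_linkages(self):
        grid = simulate_hqi_grid(20, 20, n_bumps=1, bump_width=2.5, seed=2)
        net = corridor_network(grid)
        assert net.summary["n_cores"] == 1
        assert net.summary["n_linkages"] == 0

    def test_three_cores_give_three_pairwise_linkages(self):
        grid = simulate_hqi_grid(40, 40, n_bumps=3, bump_width=2.5, seed=19)
        net = corridor_network(grid, pair_policy="all")
        assert net.summary["n_cores"] == 3
        assert net.summary["n_linkages"] == 3

    def test_neighbor_policy_never_adds_linkages(self):
        grid = simulate_hqi_grid(40, 40, n_bumps=4, bump_width=2.0, seed=23)
        all_pairs = corridor_network(grid, pair_policy="all")
        neighbors = corridor_network(grid, pair_policy="neighbors")
        assert neighbors.summary["n_linkages"] <= all_pairs.summary["n_linkages"]


class TestAsciiGrid:
    def test_round_trip_preserves_values_and_nodata(self, tmp_path):
        grid = simulate_hqi_grid(8, 10, n_bumps=1, bump_width=2.0, seed=3,
                                 cell_size=250.0)
        grid.values[0, 0] = np.nan
        path = tmp_path / "hqi.asc"
        write_ascii_grid(grid, path)
        back = read_ascii_grid(path)
        assert back.cell_size == 250.0
        assert np.isnan(back.values[0, 0])
        assert np.allclose(back.values, grid.values, equal_nan=True, atol=1e-6)
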