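"""Habitat-connectivity stage: quartile core areas and least-cost corridors.

Given a habitat-quality-index (HQI) raster in [0, 1], cells at or above the
75th percentile of the non-nodata values (the fourth quartile, Q4) form the
core area; 8-connected components of core cells are the core patches. A
resistance surface is derived by linear inversion to the conventional
[1, 100] range, r = 1 + 99 * (1 - HQI), with nodata cells impassable.
Corridors are least-cost routes over 8-connected moves where stepping from
cell i to an adjacent cell j costs ``step_length * (r_i + r_j) / 2``
(average-node-cost convention), with ``step_length`` equal to the cell size
orthogonally and cell size * sqrt(2) diagonally. Patch-to-patch cost is the
minimum over all source/target cell pairs (multi-source Dijkstra).

Rasters interchange as ESRI ASCII grids; corridor networks export as a cost
matrix plus per-corridor cell paths.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from straitpop.errors import EmptyGridError

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class HQIGrid:
    """Habitat-quality raster. ``values`` holds NaN for nodata cells."""

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # lower-left corner (x, y)
    nodata_value: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("HQI grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("HQI values must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class CorePatch:
    """One 8-connected component of Q4 core cells."""

    patch_id: int
    cells: list[tuple[int, int]]
    area_cells: int
    centroid: tuple[float, float]


@dataclass
class Corridor:
    """Least-cost linkage between two core patches."""

    patch_a: int
    patch_b: int
    path: list[tuple[int, int]] | None
    cost: float

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.cost)


@dataclass
class CorridorNetwork:
    cores: list[CorePatch]
    corridors: list[Corridor]
    threshold: float
    summary: dict = field(default_factory=dict)


def read_ascii_grid(path) -> HQIGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize
    header, rows listed north to south)."""
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key}")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:].__iter__())
    data = np.atleast_2d(data).reshape(int(header["nrows"]), int(header["ncols"]))
    values = np.where(data == nodata, np.nan, data)
    return HQIGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata_value=nodata,
    )


def write_ascii_grid(grid: HQIGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]}\n")
        fh.write(f"yllcorner {grid.origin[1]}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {grid.nodata_value}\n")
        out = np.where(np.isfinite(grid.values), grid.values, grid.nodata_value)
        for row in out:
            fh.write(" ".join(format(v, ".6g") for v in row) + "\n")


def core_areas(grid: HQIGrid, *, quantile: float = 0.75) -> list[CorePatch]:
    """Extract Q4 core patches.

    The threshold is the ``quantile`` (default 75th percentile,
    linear-interpolation definition) of the non-nodata HQI values; cells at
    or above it are core. Patches are 8-connected components labeled in
    row-major discovery order.
    """
    finite = np.isfinite(grid.values)
    if not finite.any():
        raise EmptyGridError("grid has no non-nodata cells")
    threshold = float(np.quantile(grid.values[finite], quantile))
    core_mask = finite & (grid.values >= threshold)
    labels, n_patches = ndimage.label(core_mask, structure=np.ones((3, 3), dtype=int))
    patches = []
    for pid in range(1, n_patches + 1):
        rows, cols = np.nonzero(labels == pid)
        cells = list(zip(rows.tolist(), cols.tolist()))
        patches.append(
            CorePatch(
                patch_id=pid,
                cells=cells,
                area_cells=len(cells),
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    return patches


def core_threshold(grid: HQIGrid, *, quantile: float = 0.75) -> float:
    finite = np.isfinite(grid.values)
    if not finite.any():
        raise EmptyGridError("grid has no non-nodata cells")
    return float(np.quantile(grid.values[finite], quantile))


def resistance_surface(grid: HQIGrid) -> np.ndarray:
    """Linear inversion of HQI to resistance in [1, 100]; nodata cells get
    infinite resistance (impassable)."""
    r = 1.0 + 99.0 * (1.0 - grid.values)
    return np.where(np.isfinite(grid.values), r, np.inf)


def _dijkstra_from_patch(
    resistance: np.ndarray, source_cells, cell_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source Dijkstra over the 8-connected grid.

    Returns (cost, predecessor) arrays; predecessor holds the flat index of
    the previous cell on the cheapest path (-1 at sources/unreached). Heap
    entries are keyed (cost, row, col) so ties resolve deterministically.
    """
    n_rows, n_cols = resistance.shape
    cost = np.full((n_rows, n_cols), np.inf)
    pred = np.full((n_rows, n_cols), -1, dtype=np.int64)
    done = np.zeros((n_rows, n_cols), dtype=bool)
    heap = []
    for r, c in sorted(source_cells):
        if math.isfinite(resistance[r, c]):
            cost[r, c] = 0.0
            heapq.heappush(heap, (0.0, r, c))
    diag = cell_size * math.sqrt(2.0)
    while heap:
        d, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        for dr, dc in _EIGHT:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols) or done[nr, nc]:
                continue
            rr = resistance[nr, nc]
            if not math.isfinite(rr):
                continue
            step = diag if dr and dc else cell_size
            nd = d + step * (resistance[r, c] + rr) / 2.0
            if nd < cost[nr, nc]:
                cost[nr, nc] = nd
                pred[nr, nc] = r * n_cols + c
                heapq.heappush(heap, (nd, nr, nc))
    return cost, pred


def _extract_path(pred: np.ndarray, end: tuple[int, int]) -> list[tuple[int, int]]:
    n_cols = pred.shape[1]
    path = [end]
    r, c = end
    while pred[r, c] >= 0:
        flat = pred[r, c]
        r, c = int(flat // n_cols), int(flat % n_cols)
        path.append((r, c))
    path.reverse()
    return path


def least_cost_paths(
    resistance: np.ndarray,
    cores: list[CorePatch],
    *,
    cell_size: float = 1.0,
) -> list[Corridor]:
    """Least-cost corridor for every core pair.

    Unreachable pairs are kept with infinite cost rather than dropped. The
    target cell for path extraction is the minimum-cost cell of the target
    patch (ties broken by row-major order).
    """
    if len(cores) < 2:
        return []
    corridors = []
    runs = {p.patch_id: _dijkstra_from_patch(resistance, p.cells, cell_size) for p in cores}
    by_id = {p.patch_id: p for p in cores}
    for a, b in itertools.combinations(sorted(by_id), 2):
        cost_a, pred_a = runs[a]
        cells_b = sorted(by_id[b].cells)
        costs = [cost_a[r, c] for r, c in cells_b]
        best = int(np.argmin(costs))
        total = costs[best]
        path = _extract_path(pred_a, cells_b[best]) if math.isfinite(total) else None
        corridors.append(Corridor(patch_a=a, patch_b=b, path=path, cost=float(total)))
    return corridors


def corridor_network(
    grid: HQIGrid, *, quantile: float = 0.75, pair_policy: str = "all"
) -> CorridorNetwork:
    """Full connectivity stage: Q4 cores, resistance, least-cost corridors.

    ``pair_policy='all'`` links every reachable core pair;
    ``'neighbors'`` keeps only corridors whose path crosses no third core
    patch (a neighbor-limited network).
    """
    cores = core_areas(grid, quantile=quantile)
    resistance = resistance_surface(grid)
    corridors = least_cost_paths(resistance, cores, cell_size=grid.cell_size)
    if pair_policy == "neighbors":
        cell_owner = {}
        for p in cores:
            for cell in p.cells:
                cell_owner[cell] = p.patch_id
        kept = []
        for cor in corridors:
            if cor.path is None:
                kept.append(cor)
                continue
            third = {
                cell_owner[c]
                for c in cor.path
                if c in cell_owner and cell_owner[c] not in (cor.patch_a, cor.patch_b)
            }
            if not third:
                kept.append(cor)
        corridors = kept
    elif pair_policy != "all":
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    n_link = sum(1 for c in corridors if c.reachable)
    return CorridorNetwork(
        cores=cores,
        corridors=corridors,
        threshold=core_threshold(grid, quantile=quantile),
        summary={"n_cores": len(cores), "n_linkages": n_link, "pair_policy": pair_policy},
    )
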