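"""Per-tile Delaunay cell networks and connection-frequency vectors.

A slide is a point pattern of typed cell centroids (µm, origin top-left,
y increasing downward).  The slide is cut into non-overlapping square
tiles (default 200 µm, the scale of effective intercellular
communication); within each tile the cells are joined by their Delaunay
triangulation, and each edge is a "connection" between two neighbouring
cells.  With four cell classes — malignant epithelial (M), inflammatory
(I), spindle-shaped (S) and necrotic debris (N) — there are ten
unordered type pairs, and each tile is summarised by the 10-component
simplex vector of edge-type proportions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

#: The four cell classes, in canonical order (identified with 1..4).
CELL_TYPES: tuple[str, ...] = ("M", "I", "S", "N")

_TYPE_TO_INT = {t: i + 1 for i, t in enumerate(CELL_TYPES)}

#: Canonical order of the ten unordered type pairs (i >= j, 1-based).
PAIR_ORDER: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, 5) for j in range(1, i + 1)
)

N_PAIRS = len(PAIR_ORDER)  # == 10

DEFAULT_TILE_SIZE_UM = 200.0
DEFAULT_MIN_CELLS = 5


def pair_index(type_a: str, type_b: str) -> int:
    """Position of the unordered pair (type_a, type_b) in the canonical order.

    The order is (1,1),(2,1),(2,2),(3,1),(3,2),(3,3),(4,1),(4,2),(4,3),(4,4)
    over M=1, I=2, S=3, N=4, so ``pair_index`` is symmetric and bijective
    over unordered pairs with repetition.
    """
    try:
        a = _TYPE_TO_INT[type_a]
        b = _TYPE_TO_INT[type_b]
    except KeyError as err:
        raise ValueError(
            f"unknown cell type {err.args[0]!r}; expected one of {CELL_TYPES}"
        ) from None
    i, j = (a, b) if a >= b else (b, a)
    return i * (i - 1) // 2 + (j - 1)


def pair_labels() -> list[str]:
    """Human-readable labels ('M-M', 'I-M', ...) in canonical order."""
    return [f"{CELL_TYPES[i - 1]}-{CELL_TYPES[j - 1]}" for i, j in PAIR_ORDER]


@dataclass
class Tile:
    """One square tile of a slide with the cells it contains.

    Bounds are half-open: [col*w, (col+1)*w) x [row*w, (row+1)*w).
    """

    row: int
    col: int
    tile_size_um: float
    cells: pd.DataFrame  # columns x_um, y_um, cell_type

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        w = self.tile_size_um
        return (self.col * w, self.row * w, (self.col + 1) * w, (self.row + 1) * w)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class CellNetwork:
    """Delaunay graph of one tile's cells.

    ``points`` is (n, 2) µm coordinates, ``types`` the per-vertex class
    labels, ``edges`` an array of unordered vertex index pairs (a < b).
    """

    points: np.ndarray
    types: np.ndarray
    edges: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ConnectionFrequencyVector:
    """10-component edge-type proportion vector of one tile's network."""

    h: np.ndarray
    n_edges: int
    tile: Tile | None = field(default=None, repr=False)


def tile_cells(
    cells: pd.DataFrame, tile_size_um: float = DEFAULT_TILE_SIZE_UM
) -> list[Tile]:
    """Assign cells to non-overlapping square tiles; empty tiles are omitted.

    Parameters
    ----------
    cells
        Table with columns ``x_um``, ``y_um``, ``cell_type``.
    tile_size_um
        Tile edge length in µm (default 200).
    """
    if tile_size_um <= 0:
        raise ValueError("tile_size_um must be positive")
    if len(cells) == 0:
        return []
    x = np.asarray(cells["x_um"], dtype=float)
    y = np.asarray(cells["y_um"], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("cell coordinates must be finite")
    if (x < 0).any() or (y < 0).any():
        raise ValueError(
            "negative coordinates: cell maps use a top-left origin with "
            "x, y >= 0 in µm"
        )
    bad = set(cells["cell_type"]) - set(CELL_TYPES)
    if bad:
        raise ValueError(f"unknown cell types {sorted(bad)}; expected {CELL_TYPES}")
    col = np.floor(x / tile_size_um).astype(int)
    row = np.floor(y / tile_size_um).astype(int)
    tiles = []
    for (r, c), idx in cells.groupby([row, col], sort=True).groups.items():
        tiles.append(Tile(row=int(r), col=int(c), tile_size_um=tile_size_um,
                          cells=cells.loc[idx]))
    return tiles


def _dedupe_coincident(points: np.ndarray, types: np.ndarray):
    """Merge exactly coincident sites, keeping the first record's type."""
    _, first = np.unique(points, axis=0, return_index=True)
    if len(first) < len(points):
        warnings.warn(
            f"merged {len(points) - len(first)} coincident cell coordinates "
            "(first record's type kept)",
            stacklevel=3,
        )
        first = np.sort(first)
        points, types = points[first], types[first]
    return points, types


def _collinear_path_edges(points: np.ndarray) -> np.ndarray:
    """Edges of the consecutive-neighbour path along a line of points."""
    centered = points - points.mean(axis=0)
    # project onto the principal axis of the (degenerate) point cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    return np.sort(np.column_stack([order[:-1], order[1:]]), axis=1)


def delaunay_network(tile: Tile) -> CellNetwork:
    """Build the Delaunay cell network of one tile.

    Edges never cross tile boundaries (the triangulation sees only this
    tile's cells).  Degenerate inputs follow the natural 1-D limits:
    two cells give a single edge, three or more collinear cells give the
    consecutive-neighbour path.  Exactly coincident coordinates are
    merged to one vertex with a warning.
    """
    if tile.n_cells == 0:
        raise ValueError("cannot build a network on an empty tile")
    points = tile.cells[["x_um", "y_um"]].to_numpy(dtype=float)
    types = tile.cells["cell_type"].to_numpy()
    points, types = _dedupe_coincident(points, types)
    n = len(points)
    if n == 1:
        edges = np.empty((0, 2), dtype=int)
    elif n == 2:
        edges = np.array([[0, 1]])
    else:
        try:
            tri = Delaunay(points)
        except QhullError:
            # all sites collinear (or otherwise rank-deficient)
            edges = _collinear_path_edges(points)
        else:
            pairs = set()
            for simplex in tri.simplices:
                for a, b in combinations(simplex, 2):
                    pairs.add((min(a, b), max(a, b)))
            edges = np.array(sorted(pairs), dtype=int)
    return CellNetwork(points=points, types=types, edges=edges)


def connection_frequencies(network: CellNetwork) -> ConnectionFrequencyVector:
    """Edge-type proportions h of a cell network.

    h[pair_index(i, j)] is the fraction of edges joining a type-i and a
    type-j cell; the components sum to 1 whenever the network has edges,
    and the vector is all-zero (with n_edges = 0) otherwise.
    """
    counts = np.zeros(N_PAIRS)
    for a, b in network.edges:
        counts[pair_index(network.types[a], network.types[b])] += 1
    n_edges = int(counts.sum())
    h = counts / n_edges if n_edges > 0 else counts
    return ConnectionFrequencyVector(h=h, n_edges=n_edges)


def tile_frequency_table(
    cells: pd.DataFrame,
    tile_size_um: float = DEFAULT_TILE_SIZE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Per-tile connection-frequency table for one or more slides.

    Returns one row per non-empty tile with columns ``case_id``, ``row``,
    ``col``, ``n_cells``, ``n_edges``, ``phenotyped`` and ``h_1``..``h_10``.
    Tiles with fewer than ``min_cells`` cells get ``phenotyped = False``
    and NaN frequencies: tiny networks produce unstable proportion
    vectors and are excluded from phenotyping.
    """
    if "case_id" not in cells.columns:
        cells = cells.assign(case_id="case")
    rows = []
    for case_id, case_cells in cells.groupby("case_id", sort=True):
        for tile in tile_cells(case_cells, tile_size_um):
            rec = {
                "case_id": case_id,
                "row": tile.row,
                "col": tile.col,
                "n_cells": tile.n_cells,
            }
            if tile.n_cells >= min_cells:
                cfv = connection_frequencies(delaunay_network(tile))
                rec["n_edges"] = cfv.n_edges
                rec["phenotyped"] = cfv.n_edges > 0
                h = cfv.h if cfv.n_edges > 0 else np.full(N_PAIRS, np.nan)
            else:
                rec["n_edges"] = 0
                rec["phenotyped"] = False
                h = np.full(N_PAIRS, np.nan)
            rec.update({f"h_{k + 1}": h[k] for k in range(N_PAIRS)})
            rows.append(rec)
    columns = ["case_id", "row", "col", "n_cells", "n_edges", "phenotyped"] + [
        f"h_{k + 1}" for k in range(N_PAIRS)
    ]
    table = pd.DataFrame(rows, columns=columns)
    n_skip = int((~table["phenotyped"]).sum()) if len(table) else 0
    if n_skip:
        logger.info("excluded %d tiles below min_cells=%d from phenotyping",
                    n_skip, min_cells)
    return table
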