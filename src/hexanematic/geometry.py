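"""Polygonal cell and monolayer containers.

All coordinates are in micrometres, in an image-like frame (x to the right,
y increasing downward, origin at the top-left corner of the field of view).
Vertex lists are stored with positive shoelace signed area, which is the
package-wide convention for "counterclockwise" in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as an (V, 2) array."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid (centre of mass of the uniform lamina)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class CellPolygon:
    """One segmented cell: an ordered simple polygon plus its adjacency.

    ``vertices`` is an (V, 2) float array in μm; the constructor normalises
    the winding so the shoelace area is positive.  ``neighbor_ids`` holds the
    ids of cells sharing a junction edge; the relation is symmetric at the
    :class:`Monolayer` level.
    """

    cell_id: int
    vertices: np.ndarray
    neighbor_ids: set[int] = field(default_factory=set)
    is_border: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(
                f"cell {self.cell_id}: need an (V>=3, 2) vertex array, got {v.shape}"
            )
        if signed_area(v) < 0:
            v = v[::-1].copy()
        if signed_area(v) <= 0:
            raise ValueError(f"cell {self.cell_id}: zero polygon area")
        self.vertices = v

    @cached_property
    def area(self) -> float:
        return signed_area(self.vertices)

    @cached_property
    def perimeter(self) -> float:
        return polygon_perimeter(self.vertices)

    @cached_property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.vertices)

    @cached_property
    def vertex_mean(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class Monolayer:
    """A confluent sheet of cells inside a rectangular field of view.

    ``box`` is (width, height) in μm.  ``rcc`` is the mean centroid distance
    between interior neighbour pairs; it is filled in lazily by
    :func:`hexanematic.shape.mean_cell_cell_distance` and cached here because
    every coarse-graining scale downstream is expressed in units of it.
    """

    cells: list[CellPolygon]
    box: tuple[float, float]
    pixel_size: float | None = None
    rcc: float | None = None

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate cell_ids in monolayer")
        self._by_id = {c.cell_id: c for c in self.cells}
        for c in self.cells:
            for nb in c.neighbor_ids:
                if nb not in self._by_id:
                    raise ValueError(
                        f"cell {c.cell_id} lists unknown neighbor {nb}"
                    )
                if c.cell_id not in self._by_id[nb].neighbor_ids:
                    raise ValueError(
                        f"asymmetric adjacency between {c.cell_id} and {nb}"
                    )

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: int) -> CellPolygon:
        return self._by_id[cell_id]

    @property
    def interior_cells(self) -> list[CellPolygon]:
        return [c for c in self.cells if not c.is_border]

    def neighbor_pairs(self, interior_only: bool = True) -> list[tuple[int, int]]:
        """Unordered neighbour pairs, each counted once."""
        pairs = set()
        for c in self.cells:
            if interior_only and c.is_border:
                continue
            for nb in c.neighbor_ids:
                other = self._by_id[nb]
                if interior_only and other.is_border:
                    continue
                pairs.add(tuple(sorted((c.cell_id, nb))))
        return sorted(pairs)
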