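"""Per-cell shape descriptors.

Two descriptors drive the whole analysis:

* the shape index ``p0 = P / sqrt(A)``, a scalar elongation measure
  (3.7224 for a regular hexagon, 4.0 for a square, larger for stretched
  cells); and
* the complex p-fold shape function

  .. math::

      \\gamma_p = \\frac{\\sum_v |r_v|^p e^{i p \\phi_v}}{\\sum_v |r_v|^p},

  where ``r_v`` is the v-th vertex position relative to the cell's centre
  of mass and ``phi_v`` its polar angle.  ``|gamma_p| <= 1`` measures the
  resemblance to a regular p-gon (1 for a regular hexagon at p = 6) and
  ``Arg(gamma_p)/p`` is the cell's p-fold orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CellPolygon, Monolayer

#: supported conventions for the "centre of mass" reference point of gamma_p
REFERENCE_POINTS = ("area-centroid", "vertex-mean")


def shape_index(polygon: CellPolygon) -> float:
    """Perimeter over square root of area; dimensionless and scale-invariant."""
    a = polygon.area
    if a <= 0:
        raise ValueError(f"cell {polygon.cell_id}: zero area")
    return polygon.perimeter / math.sqrt(a)


def gamma_p(
    polygon: CellPolygon, p: int, reference: str = "area-centroid"
) -> complex:
    """Complex p-fold shape function of one polygon.

    ``reference`` selects which point plays the role of the centre of mass:
    the area centroid (default) or the arithmetic mean of the vertices.
    """
    if p < 1:
        raise ValueError(f"p must be a positive integer, got {p}")
    if reference == "area-centroid":
        ref = polygon.centroid
    elif reference == "vertex-mean":
        ref = polygon.vertex_mean
    else:
        raise ValueError(f"unknown reference {reference!r}; use one of {REFERENCE_POINTS}")
    r = polygon.vertices - ref
    mod = np.linalg.norm(r, axis=1)
    if not np.any(mod > 0):
        raise ValueError(f"cell {polygon.cell_id}: all vertices coincide with reference")
    phi = np.arctan2(r[:, 1], r[:, 0])
    w = mod**p
    return complex(np.sum(w * np.exp(1j * p * phi)) / np.sum(w))


def orientation(gamma: complex, p: int) -> float:
    """p-fold orientation ``Arg(gamma_p)/p``, folded into [0, 2*pi/p)."""
    return float(np.angle(gamma) / p) % (2.0 * math.pi / p)


@dataclass
class ShapeRecord:
    """Shape descriptors of one cell for a set of symmetry indices p."""

    cell_id: int
    p0: float
    gamma: dict[int, complex]
    orientation: dict[int, float]


def compute_shape_records(
    monolayer: Monolayer,
    ps: tuple[int, ...] = (2, 6),
    reference: str = "area-centroid",
    interior_only: bool = True,
) -> dict[int, ShapeRecord]:
    """Shape records keyed by cell_id (border cells skipped by default)."""
    cells = monolayer.interior_cells if interior_only else monolayer.cells
    records = {}
    for c in cells:
        g = {p: gamma_p(c, p, reference) for p in ps}
        records[c.cell_id] = ShapeRecord(
            cell_id=c.cell_id,
            p0=shape_index(c),
            gamma=g,
            orientation={p: orientation(g[p], p) for p in ps},
        )
    return records


def ensemble_average(records, p: int) -> float:
    """Mean of |gamma_p| over cells: magnitude first, then average.

    ``records`` may be a dict (as returned by :func:`compute_shape_records`)
    or any iterable of :class:`ShapeRecord`.
    """
    recs = list(records.values()) if isinstance(records, dict) else list(records)
    if not recs:
        raise ValueError("empty ensemble")
    return float(np.mean([abs(r.gamma[p]) for r in recs]))


def mean_cell_cell_distance(monolayer: Monolayer, store: bool = True) -> float:
    """Mean centroid-to-centroid distance over interior neighbour pairs.

    Each unordered pair is counted once; pairs involving a border cell are
    excluded so the estimate is unbiased by the clipped boundary polygons.
    """
    pairs = monolayer.neighbor_pairs(interior_only=True)
    if not pairs:
        raise ValueError("no interior neighbor pairs; cannot estimate R_cc")
    d = [
        float(np.linalg.norm(monolayer.cell(a).centroid - monolayer.cell(b).centroid))
        for a, b in pairs
    ]
    rcc = float(np.mean(d))
    if store:
        monolayer.rcc = rcc
    return rcc


def neighbor_distribution(monolayer: Monolayer) -> dict[int, float]:
    """Probability distribution of the nearest-neighbour count of interior cells."""
    interior = monolayer.interior_cells
    if not interior:
        return {}
    counts = np.array([len(c.neighbor_ids) for c in interior])
    ks, ns = np.unique(counts, return_counts=True)
    return {int(k): float(n) / len(interior) for k, n in zip(ks, ns)}
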