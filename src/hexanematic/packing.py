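"""Disk packing on the triangular lattice.

Rigid disks arranged in a honeycomb (triangular) lattice cover the fraction
``pi * sqrt(3) / 6 ~ 0.91`` of the plane; the remaining ~0.09 is gap space
that only deformable particles can fill, which is why confluent cells can
reach packing fraction 1 while staying nearly six-fold.
"""

from __future__ import annotations

import math

import numpy as np

#: lattice vectors of the unit-spacing triangular lattice
_A1 = np.array([1.0, 0.0])
_A2 = np.array([0.5, math.sqrt(3.0) / 2.0])


def honeycomb_packing_fraction() -> float:
    """Closed form: one disk of radius 1/2 per primitive cell of area
    sqrt(3)/2, hence pi/4 / (sqrt(3)/2) = pi*sqrt(3)/6."""
    return (math.pi / 4.0) / (math.sqrt(3.0) / 2.0)


def honeycomb_gap_fraction() -> float:
    return 1.0 - honeycomb_packing_fraction()


def honeycomb_packing_fraction_mc(n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo estimate on one primitive cell.

    Uniform samples in the rhombus spanned by the lattice vectors are tested
    for coverage by the touching disks (radius 1/2) centred at the four cell
    corners; for the unit triangular lattice the nearest lattice point to
    any point of the rhombus is one of its corners, so four distances
    suffice.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples)
    v = rng.random(n_samples)
    pts = np.outer(u, _A1) + np.outer(v, _A2)
    corners = np.array([[0, 0], _A1, _A2, _A1 + _A2], dtype=float)
    d2 = ((pts[:, None, :] - corners[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return float(np.mean(d2 <= 0.25))
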