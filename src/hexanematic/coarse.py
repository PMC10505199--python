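"""Scale-dependent shape parameter and the hexanematic crossover.

The per-cell shape function ``gamma_p`` is coarse-grained into

    Gamma_p(r, R) = (1/N_disk) * sum_c gamma_p(r_c) * Theta(R - |r - r_c|),

the mean of ``gamma_p`` over cells whose centre of mass lies strictly inside
a disk of radius R around the sampling point r.  Sampling points form a
square grid of spacing R_cc/2 inside a fixed field of view (124 μm by
default) and the radius ladder grows in steps of R_cc/2.  The grid-averaged
magnitude ``|Gamma_p(R)|-bar`` quantifies p-atic order at scale R; the
hexanematic crossover R_x is the radius where the hexatic and nematic
profiles intersect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Monolayer
from .shape import ShapeRecord, mean_cell_cell_distance

DEFAULT_FOV_UM = 124.0


@dataclass(frozen=True)
class Grid:
    """Square sampling grid: ``point(i, j) = origin + spacing * (j, i)``."""

    origin: tuple[float, float]
    spacing: float
    nx: int
    ny: int

    @property
    def points(self) -> np.ndarray:
        """(ny*nx, 2) array of positions, row-major (i slow, j fast)."""
        jj, ii = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        x = self.origin[0] + self.spacing * jj
        y = self.origin[1] + self.spacing * ii
        return np.column_stack([x.ravel(), y.ravel()])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass
class CoarseField:
    """Gamma_p on the grid for a ladder of radii.

    ``values`` has shape (n_radii, ny, nx); grid points whose disk contains
    no cell are NaN and are excluded from the grid average.
    """

    p: int
    rcc: float
    radii: np.ndarray
    grid: Grid
    values: np.ndarray

    @property
    def radii_norm(self) -> np.ndarray:
        return self.radii / self.rcc


@dataclass
class CrossoverProfile:
    """Hexanematic difference profile and its crossover scale.

    ``delta`` is ``|Gamma_6|-bar - |Gamma_2|-bar`` per ladder radius;
    ``r_cross`` is the linearly interpolated root in units of R_cc, or None
    when the profile never changes sign (see ``regime``).
    """

    radii_norm: np.ndarray
    delta: np.ndarray
    r_cross: float | None
    regime: str


def make_grid(monolayer: Monolayer, fov: float = DEFAULT_FOV_UM) -> Grid:
    """Square grid of spacing R_cc/2 spanning a centred field of view.

    The field of view is clipped to the monolayer box when smaller.  The
    grid nodes are sampling points, not cell centres.
    """
    rcc = monolayer.rcc or mean_cell_cell_distance(monolayer)
    spacing = rcc / 2.0
    fov_w = min(fov, monolayer.box[0])
    fov_h = min(fov, monolayer.box[1])
    if fov_w < spacing or fov_h < spacing:
        raise ValueError(
            f"field of view {fov_w:.1f} x {fov_h:.1f} μm smaller than one "
            f"grid cell ({spacing:.1f} μm)"
        )
    nx = int(math.floor(fov_w / spacing)) + 1
    ny = int(math.floor(fov_h / spacing)) + 1
    origin = (
        (monolayer.box[0] - fov_w) / 2.0,
        (monolayer.box[1] - fov_h) / 2.0,
    )
    return Grid(origin=origin, spacing=spacing, nx=nx, ny=ny)


def radius_ladder(
    rcc: float,
    fov: float = DEFAULT_FOV_UM,
    max_radius: float | None = None,
) -> np.ndarray:
    """Radii R_cc/2, R_cc, 3R_cc/2, ... up to half the field-of-view diagonal
    (or ``max_radius`` when given)."""
    if max_radius is None:
        max_radius = fov * math.sqrt(2.0) / 2.0
    step = rcc / 2.0
    n = int(math.floor(max_radius / step))
    if n < 1:
        raise ValueError("max_radius smaller than one ladder step")
    return step * np.arange(1, n + 1)


def coarse_gamma(
    monolayer: Monolayer,
    records: dict[int, ShapeRecord],
    p: int,
    radii: np.ndarray | float,
    grid: Grid | None = None,
    fov: float = DEFAULT_FOV_UM,
) -> CoarseField:
    """Evaluate Gamma_p on the grid for each radius of the ladder.

    Only interior cells contribute (border polygons are clipped artefacts);
    the Heaviside factor is strict, so a cell whose centre lies exactly on
    the disk boundary is excluded.
    """
    rcc = monolayer.rcc or mean_cell_cell_distance(monolayer)
    if grid is None:
        grid = make_grid(monolayer, fov=fov)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("coarse-graining radii must be positive")

    interior = [c for c in monolayer.interior_cells if c.cell_id in records]
    centroids = np.array([c.centroid for c in interior])
    gam = np.array([records[c.cell_id].gamma[p] for c in interior])
    pts = grid.points
    values = np.full((len(radii), len(pts)), np.nan + 0j, dtype=complex)
    if len(interior):
        tree = cKDTree(centroids)
        for k, R in enumerate(radii):
            for n, idx in enumerate(tree.query_ball_point(pts, R)):
                if not idx:
                    continue
                d = np.linalg.norm(centroids[idx] - pts[n], axis=1)
                sel = np.asarray(idx)[d < R]  # Theta(0) = 0: strict inequality
                if len(sel):
                    values[k, n] = gam[sel].mean()
    return CoarseField(
        p=p, rcc=rcc, radii=radii, grid=grid,
        values=values.reshape(len(radii), grid.ny, grid.nx),
    )


def mean_abs_profile(field: CoarseField) -> np.ndarray:
    """Grid average of |Gamma_p| per radius (magnitude first, then average).

    Radii at which every grid point is missing yield NaN with a warning.
    """
    mags = np.abs(field.values).reshape(len(field.radii), -1)
    out = np.empty(len(field.radii))
    for k in range(len(field.radii)):
        m = mags[k][np.isfinite(mags[k])]
        if len(m) == 0:
            warnings.warn(
                f"all grid points empty at R = {field.radii[k]:.2f} μm; "
                "radius dropped from the profile"
            )
            out[k] = np.nan
        else:
            out[k] = m.mean()
    return out


def crossover_scale(
    radii: np.ndarray,
    profile6: np.ndarray,
    profile2: np.ndarray,
    rcc: float,
) -> CrossoverProfile:
    """Locate R_x where the hexatic profile first drops to the nematic one.

    Scans ``delta = |Gamma_6|-bar - |Gamma_2|-bar`` along the ladder for the
    first sign change from positive to non-positive and returns the linear
    interpolation root normalised by R_cc.  When delta never changes sign
    the result is None with a diagnostic regime string.
    """
    radii = np.asarray(radii, dtype=float)
    profile6 = np.asarray(profile6, dtype=float)
    profile2 = np.asarray(profile2, dtype=float)
    if radii.shape != profile6.shape or radii.shape != profile2.shape:
        raise ValueError("radius ladders of the two profiles do not match")
    delta = profile6 - profile2
    ok = np.isfinite(delta)
    r, d = radii[ok] / rcc, delta[ok]
    if len(d) == 0:
        raise ValueError("empty profiles")
    if d[0] <= 0:
        return CrossoverProfile(r, d, None, "nematic-dominated at all scales")
    for i in range(len(d) - 1):
        if d[i] > 0 and d[i + 1] <= 0:
            frac = d[i] / (d[i] - d[i + 1])
            return CrossoverProfile(
                r, d, float(r[i] + frac * (r[i + 1] - r[i])), "crossover"
            )
    return CrossoverProfile(r, d, None, "hexatic-dominated at all scales")


def pooled_crossover(
    profiles: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]],
) -> CrossoverProfile:
    """Crossover of seed-averaged profiles.

    ``profiles`` holds ``(radii, profile6, profile2, rcc)`` per monolayer.
    Each ladder is normalised by its own R_cc, truncated to the shortest
    ladder, and the profiles are averaged before locating the crossover —
    the pooled (per-ensemble) estimator.
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    n = min(len(r) for r, _, _, _ in profiles)
    rn = np.mean([r[:n] / rcc for r, _, _, rcc in profiles], axis=0)
    p6 = np.mean([p[:n] for _, p, _, _ in profiles], axis=0)
    p2 = np.mean([p[:n] for _, _, p, _ in profiles], axis=0)
    return crossover_scale(rn, p6, p2, 1.0)


def hexanematic_profile(
    monolayer: Monolayer,
    records: dict[int, ShapeRecord],
    fov: float = DEFAULT_FOV_UM,
    max_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, CrossoverProfile]:
    """Convenience pipeline: ladder, both profiles, crossover.

    Returns ``(radii, profile6, profile2, crossover)``.
    """
    rcc = monolayer.rcc or mean_cell_cell_distance(monolayer)
    grid = make_grid(monolayer, fov=fov)
    radii = radius_ladder(rcc, fov=min(fov, *monolayer.box), max_radius=max_radius)
    prof = {}
    for p in (2, 6):
        field = coarse_gamma(monolayer, records, p, radii, grid=grid)
        prof[p] = mean_abs_profile(field)
    cross = crossover_scale(radii, prof[6], prof[2], rcc)
    return radii, prof[6], prof[2], cross
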