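"""Synthetic confluent monolayers.

Ground-truth tissue is emulated as the Voronoi tessellation of a jittered
triangular lattice: the lattice supplies the honeycomb baseline that dense
epithelia approach, the jitter destroys positional order the way biological
variability does, and an area-preserving uniaxial stretch of the seed
pattern mimics the elongated phenotype of adhesion-depleted cells.  The
tessellation is clipped to a rectangular box, so the tiling is confluent by
construction (packing fraction 1).  Junction images are rendered from the
ground-truth polygons as bright ridges with optional blur and additive
Gaussian noise, so segmentation accuracy can be measured exactly.

RNG stream order (single integer ``seed`` per config): stream 0 drives the
seed-point jitter, stream 1 the rendering noise, stream 2 the elastic warp
modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon as ShapelyPolygon, box as shapely_box

from .geometry import CellPolygon, Monolayer

#: clipped slivers below this area (μm^2) are discarded as numerical noise
_MIN_CELL_AREA = 1e-9


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic monolayer.

    Lengths in μm; ``elongation >= 1`` is the target major/minor aspect
    ratio of the cells (1 = isotropic), realised as an area-preserving
    uniaxial stretch by (sqrt(e), 1/sqrt(e)) along ``elongation_axis``;
    ``jitter`` in [0, 1] displaces each lattice point by a uniform draw
    from a disk of radius ``jitter * spacing / 2``; ``warp`` is the rms
    local rotation (radians) of a smooth elastic displacement field with
    wavelengths from ``warp_wavelength`` (default 2 R_cc) up to 3x that,
    which makes orientational order decay with distance.
    """

    box_width: float = 180.0
    box_height: float = 180.0
    target_rcc: float = 16.0
    elongation: float = 1.0
    elongation_axis: float = 0.0
    jitter: float = 0.0
    warp: float = 0.0
    warp_wavelength: float | None = None
    seed: int = 0
    pixel_size: float = 0.5
    line_width_px: int = 2
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.elongation < 1:
            raise ValueError(f"elongation must be >= 1, got {self.elongation}")
        if not 0 <= self.jitter <= 1:
            raise ValueError(f"jitter must lie in [0, 1], got {self.jitter}")
        for name in ("box_width", "box_height", "target_rcc", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be non-negative")
        if self.warp < 0:
            raise ValueError("warp (rms local rotation, rad) must be non-negative")
        if self.warp_wavelength is not None and self.warp_wavelength <= 0:
            raise ValueError("warp_wavelength must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _stretch_matrix(e: float, axis: float) -> np.ndarray:
    """Area-preserving stretch by factors (e, 1/e) along/across ``axis``."""
    c, s = math.cos(axis), math.sin(axis)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag([e, 1.0 / e]) @ rot.T


def _lattice_points(
    x0: float, x1: float, y0: float, y1: float, a: float, jitter: float, seed: int
) -> np.ndarray:
    """Jittered triangular lattice of spacing ``a`` covering the rectangle."""
    row_h = a * math.sqrt(3.0) / 2.0
    rows = np.arange(math.floor(y0 / row_h), math.ceil(y1 / row_h) + 1)
    cols = np.arange(math.floor(x0 / a) - 1, math.ceil(x1 / a) + 1)
    jj, ii = np.meshgrid(cols, rows)
    x = jj * a + (ii % 2) * (a / 2.0)
    y = ii * row_h
    pts = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    if jitter > 0:
        rng = np.random.default_rng([0, seed])
        rmax = jitter * a / 2.0
        u = rng.random(len(pts))
        theta = rng.random(len(pts)) * 2.0 * math.pi
        rad = rmax * np.sqrt(u)
        pts = pts + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    keep = (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
    return pts[keep]


def _warp_points(pts: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Smooth, long-wavelength transverse displacement field (RNG stream 2).

    A sum of 12 random sinusoidal shear modes with log-spaced wavelengths
    between ``warp_wavelength`` (default 2 R_cc) and 3x that, whose
    local rotation ``omega = (d_x u_y - d_y u_x)/2`` has rms ``config.warp``
    radians in total.  The
    local rotation turns the p-fold phase of nearby cells by ``p * omega``,
    so six-fold orientational coherence decays markedly faster with
    distance than two-fold coherence — the elastic-disorder mechanism
    behind scale-dependent p-atic order in a crystal-like packing.
    """
    if config.warp == 0:
        return pts
    lam_min = config.warp_wavelength or 2.0 * config.target_rcc
    lam_max = 3.0 * lam_min
    m = 12
    rng = np.random.default_rng([2, config.seed])
    lam = np.exp(rng.uniform(math.log(lam_min), math.log(lam_max), m))
    ang = rng.random(m) * 2.0 * math.pi
    phase = rng.random(m) * 2.0 * math.pi
    # transverse modes: rms rotation per mode is A*k/(2*sqrt(2)); equal
    # rotation variance per mode across log-spaced wavelengths gives the
    # gradual, broad-band loss of orientational coherence of a soft 2-D
    # crystal; m modes add in quadrature -> sigma_omega = A*k*sqrt(m/8)
    grad = config.warp * math.sqrt(8.0 / m)  # A*k per mode
    u = np.zeros_like(pts)
    for i in range(m):
        k = 2.0 * math.pi / lam[i]
        e_par = np.array([math.cos(ang[i]), math.sin(ang[i])])
        e_perp = np.array([-e_par[1], e_par[0]])
        s = np.sin(k * (pts @ e_par) + phase[i])
        u += (grad / k) * np.outer(s, e_perp)
    return pts + u


def _check_capacity(config: GeneratorConfig) -> None:
    # one cell per lattice site, site density 2/(sqrt(3) a^2)
    w, h, a = config.box_width, config.box_height, config.target_rcc
    if w * h * 2.0 / (math.sqrt(3.0) * a * a) < 16:
        raise ValueError(f"box {w} x {h} μm holds fewer than 16 cells at R_cc = {a} μm")


def generate_seed_points(config: GeneratorConfig) -> np.ndarray:
    """Jittered, warped triangular-lattice seed points covering the box,
    then stretched by (sqrt(e), 1/sqrt(e)) about the box centre.

    Lattice spacing equals ``target_rcc`` (for the unjittered lattice the
    mean neighbour distance is exactly the spacing); points extend one
    lattice constant beyond the box so boundary Voronoi cells are clipped by
    real neighbours rather than by missing ones.
    """
    _check_capacity(config)
    a = config.target_rcc
    w, h = config.box_width, config.box_height
    pts = _warp_points(
        _lattice_points(-a, w + a, -a, h + a, a, config.jitter, config.seed), config
    )
    if config.elongation != 1.0:
        center = np.array([w / 2.0, h / 2.0])
        m = _stretch_matrix(math.sqrt(config.elongation), config.elongation_axis)
        pts = (pts - center) @ m.T + center
    return pts


def tessellate(
    points: np.ndarray,
    box: tuple[float, float],
    transform: np.ndarray | None = None,
    transform_center: np.ndarray | None = None,
) -> Monolayer:
    """Voronoi tessellation of ``points`` clipped to ``box``.

    Cells whose Voronoi polygon crosses or touches the box boundary are
    flagged ``is_border``; adjacency records every shared Voronoi edge.  The
    clipped cells partition the box exactly (confluency).

    When ``transform`` (a 2x2 matrix, applied about ``transform_center``) is
    given, the Voronoi polygons are mapped by it before clipping.  This is
    how anisotropic monolayers are built: an affine image of a confluent
    tiling is again a confluent tiling with the same adjacency, whereas the
    Voronoi diagram of anisotropically scaled seeds is not the scaled
    diagram.

    Raises ``ValueError`` naming the offending point indices when duplicate
    (or numerically coincident) seed points are present.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 16:
        raise ValueError(f"need >= 16 seed points, got {len(pts)}")
    dup = cKDTree(pts).query_pairs(1e-9)
    if dup:
        raise ValueError(f"degenerate seed points (coincident pairs): {sorted(dup)[:10]}")

    w, h = box
    # a distant guard ring makes every real point interior to the convex
    # hull, so all real Voronoi regions are finite and clipping is exact
    guard_r = 3.0 * max(w, h)
    ang = np.linspace(0.0, 2.0 * math.pi, 32, endpoint=False)
    guards = np.column_stack(
        [w / 2.0 + guard_r * np.cos(ang), h / 2.0 + guard_r * np.sin(ang)]
    )
    allpts = np.vstack([pts, guards])
    try:
        vor = Voronoi(allpts)
    except Exception as exc:  # qhull degeneracy (e.g. all points collinear)
        raise ValueError(f"degenerate point configuration: {exc}") from exc

    clip = shapely_box(0.0, 0.0, w, h)
    n = len(pts)
    cells: list[CellPolygon] = []
    kept_index: dict[int, int] = {}  # original point index -> cell_id
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue  # only guard-ring regions are infinite; defensive
        verts = vor.vertices[region]
        if transform is not None:
            c = transform_center if transform_center is not None else np.zeros(2)
            verts = (verts - c) @ np.asarray(transform).T + c
        poly = ShapelyPolygon(verts)
        inside = poly.intersection(clip)
        if inside.is_empty or inside.area < _MIN_CELL_AREA:
            continue
        if inside.geom_type != "Polygon":
            inside = max(inside.geoms, key=lambda g: g.area)
        # touching the boundary (even without losing area) counts as border:
        # such a cell's outer neighbour was clipped away entirely
        is_border = poly.intersects(clip.exterior)
        verts = np.asarray(inside.exterior.coords)[:-1]
        cid = len(cells)
        kept_index[i] = cid
        cells.append(
            CellPolygon(cell_id=cid, vertices=verts, is_border=is_border)
        )

    for p1, p2 in vor.ridge_points:
        if p1 < n and p2 < n and p1 in kept_index and p2 in kept_index:
            a, b = kept_index[p1], kept_index[p2]
            cells[a].neighbor_ids.add(b)
            cells[b].neighbor_ids.add(a)

    return Monolayer(cells=cells, box=(w, h))


def render_junction_image(
    monolayer: Monolayer, config: GeneratorConfig
) -> np.ndarray:
    """Rasterise cell boundaries as bright ridges; returns a float image.

    Ridge amplitude is 1.0 before blur; Gaussian noise of sd ``noise_sd`` is
    added afterwards.  Pixel (row, col) covers the μm square centred at
    ``((col + 0.5) * pixel_size, (row + 0.5) * pixel_size)``.
    """
    from skimage.draw import line as draw_line
    from skimage.morphology import dilation, disk
    from scipy.ndimage import gaussian_filter

    ps = config.pixel_size
    if config.target_rcc / ps < 8:
        raise ValueError(
            f"pixel size {ps} μm/px too coarse: cell diameter below 8 px"
        )
    height = int(round(monolayer.box[1] / ps))
    width = int(round(monolayer.box[0] / ps))
    mask = np.zeros((height, width), dtype=bool)

    def to_px(pt):
        c = int(round(pt[0] / ps - 0.5))
        r = int(round(pt[1] / ps - 0.5))
        return (min(max(r, 0), height - 1), min(max(c, 0), width - 1))

    for cell in monolayer.cells:
        v = cell.vertices
        for k in range(len(v)):
            r0, c0 = to_px(v[k])
            r1, c1 = to_px(v[(k + 1) % len(v)])
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    rad = config.line_width_px // 2
    if rad > 0:
        mask = dilation(mask, disk(rad))

    img = mask.astype(float)
    if config.blur_sigma_px > 0:
        img = gaussian_filter(img, config.blur_sigma_px)
    if config.noise_sd > 0:
        rng = np.random.default_rng([1, config.seed])
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return img


def generate_monolayer(config: GeneratorConfig) -> Monolayer:
    """Seed points -> Voronoi tessellation, with the pixel size attached.

    For anisotropic monolayers the tessellation is built in isotropic space
    and the resulting tiling is stretched (see :func:`tessellate`), so the
    elongation knob acts directly on cell shapes.
    """
    _check_capacity(config)
    w, h = config.box_width, config.box_height
    a = config.target_rcc
    if config.elongation == 1.0:
        pts = generate_seed_points(config)
        ml = tessellate(pts, (w, h))
    else:
        center = np.array([w / 2.0, h / 2.0])
        s = math.sqrt(config.elongation)
        m = _stretch_matrix(s, config.elongation_axis)
        minv = _stretch_matrix(1.0 / s, config.elongation_axis)
        corners = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
        pre = (corners - center) @ minv.T + center
        pts = _warp_points(
            _lattice_points(
                pre[:, 0].min() - a, pre[:, 0].max() + a,
                pre[:, 1].min() - a, pre[:, 1].max() + a,
                a, config.jitter, config.seed,
            ),
            config,
        )
        ml = tessellate(pts, (w, h), transform=m, transform_center=center)
    ml.pixel_size = config.pixel_size
    return ml


# ---------------------------------------------------------------------------
# Study conditions for the synthetic ensembles
# ---------------------------------------------------------------------------
# Mean cell-cell distances sit at the centres of three of the density
# intervals used in the grouped analysis (2.6 μm-wide intervals starting at
# 9.7 μm).  The baseline disorder (lattice jitter 0.22, elastic warp 0.40
# rad with wavelengths 2-6 R_cc) is scale-free: in units of the cell size,
# dense and sparse monolayers share the same statistics.  Density enters
# through the cell shape instead: sparser monolayers hold more elongated
# cells (the familiar shape-index increase with cell-cell distance), which
# the study conditions encode as an aspect-ratio increment that grows with
# R_cc and fades once cells are already strongly elongated.  Elongation
# knob values cover the near-isotropic to adhesion-depleted phenotype
# range as base cell aspect ratios.

STUDY_RCC_UM: tuple[float, ...] = (13.6, 16.2, 21.4)
STUDY_ELONGATIONS: tuple[float, ...] = (1.1, 1.2, 1.3, 1.4)
STUDY_JITTER = 0.22
STUDY_WARP = 0.40  # rad
_RCC_SPAN = (9.7, 28.5)  # observed range of mean cell-cell distances, μm
_DENSITY_ASPECT = 0.30  # extra aspect ratio per unit normalized R_cc
_ASPECT_CAP = 1.45  # the density increment fades out above this aspect


def study_aspect(elongation: float, target_rcc: float) -> float:
    """Realized cell aspect ratio for a base elongation at a given density.

    Adds the density-dependent elongation increment (sparser monolayers
    hold more elongated cells), linear in R_cc over the observed span and
    fading to zero as the base aspect approaches the cap.
    """
    lo, hi = _RCC_SPAN
    t = min(max((target_rcc - lo) / (hi - lo), 0.0), 1.0)
    fade = min(max((_ASPECT_CAP - elongation) / 0.35, 0.0), 1.0)
    return elongation + _DENSITY_ASPECT * t * fade


def study_config(
    target_rcc: float,
    elongation: float = 1.0,
    seed: int = 0,
    cells: int = 200,
    **overrides,
) -> GeneratorConfig:
    """Generator config for the standard synthetic ensemble.

    The box is sized to hold ``cells`` cells at the requested density;
    jitter and warp take the study values and ``elongation`` (the base
    aspect ratio) receives the density-dependent increment of
    :func:`study_aspect`.
    """
    side = math.sqrt(cells * math.sqrt(3.0) / 2.0) * target_rcc
    kwargs = dict(
        box_width=side,
        box_height=side,
        target_rcc=target_rcc,
        elongation=study_aspect(elongation, target_rcc),
        jitter=STUDY_JITTER,
        warp=STUDY_WARP,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
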