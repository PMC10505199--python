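"""Junction-image segmentation.

A junction-marker image (e.g. ZO-1) is converted to cell polygons in three
steps mirroring classic vertex analysis: the signal is thresholded and
skeletonized; skeleton branch points — pixels where at least three cells
meet — become vertices; and each enclosed face of the junction network
becomes a cell whose ordered boundary vertices are connected by straight
lines.  Consequently the number of vertices of an interior cell equals its
number of nearest neighbours.

Pixel coordinates are (row, col), origin top-left; conversion to μm happens
exactly once, when polygons are built:
``x = (col + 0.5) * pixel_size``, ``y = (row + 0.5) * pixel_size``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import CellPolygon, Monolayer

logger = logging.getLogger(__name__)

#: single-linkage radius (px) used to merge adjacent branch pixels into one vertex
VERTEX_CLUSTER_RADIUS = 2.0
#: half-width (px) of the window used to assign a vertex to the faces it touches
VERTEX_ASSIGN_RADIUS = 3
#: faces with pixels closer than this (px) to the image edge are border faces
BORDER_MARGIN_PX = 6


def _parse_threshold(image: np.ndarray, method) -> float:
    from skimage.filters import threshold_otsu

    if method == "otsu":
        return float(threshold_otsu(image))
    if isinstance(method, str) and method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    if isinstance(method, (int, float)):
        return float(method)
    raise ValueError(f"unknown threshold method {method!r}; use 'otsu' or 'fixed:<value>'")


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_px`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def skeletonize_junctions(
    image: np.ndarray,
    threshold_method="otsu",
    min_component_px: int = 10,
) -> np.ndarray:
    """Threshold the junction signal and thin it to a 1-px skeleton.

    Connected components smaller than ``min_component_px`` (noise specks)
    are removed both before and after thinning.
    """
    from skimage.morphology import skeletonize

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.any(image > 0):
        raise ValueError("no junction signal: image is empty")
    t = _parse_threshold(image, threshold_method)
    binary = image > t
    if not np.any(binary):
        raise ValueError(f"no junction signal above threshold {t:.4g}")
    binary = _drop_small_components(binary, min_component_px)
    skel = skeletonize(binary)
    skel = _drop_small_components(skel, min_component_px)
    if not np.any(skel):
        raise ValueError("no junction signal left after cleanup")
    return skel


def cluster_points(coords: np.ndarray, radius: float) -> np.ndarray:
    """Single-linkage clustering of points; returns cluster centroids."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(coords) == 0:
        return coords
    pairs = cKDTree(coords).query_pairs(radius, output_type="ndarray")
    n = len(coords)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return np.array(
        [coords[labels == k].mean(axis=0) for k in range(labels.max() + 1)]
    )


def detect_vertices(skeleton: np.ndarray) -> np.ndarray:
    """Branch points of the skeleton, clustered into junction vertices.

    A branch pixel has >= 3 skeleton neighbours (8-connectivity).  Thinning
    often splits one biological junction into a few adjacent branch pixels,
    so branch pixels within ``VERTEX_CLUSTER_RADIUS`` px of each other are
    merged (single linkage) and each cluster is reported at its centroid.
    Returns an (n, 2) float array of (row, col) positions; possibly empty.
    """
    skel = np.asarray(skeleton, dtype=bool)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nnb = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    branch = skel & (nnb >= 3)
    coords = np.column_stack(np.nonzero(branch)).astype(float)
    if len(coords) == 0:
        return coords.reshape(0, 2)
    return cluster_points(coords, VERTEX_CLUSTER_RADIUS)


def build_polygons(
    skeleton: np.ndarray,
    vertices: np.ndarray,
    pixel_size: float = 1.0,
    min_face_area_px: int = 32,
) -> Monolayer:
    """Reconstruct the monolayer from the skeleton and its vertices.

    Enclosed faces of the junction network are found as connected components
    of the skeleton complement (4-connectivity).  Each face keeps the
    detected vertices on its boundary, ordered along the face contour and
    connected by straight lines; skeleton curvature between vertices is
    discarded.  Two faces are neighbours when their polygons share an edge
    (two consecutive vertices).  Faces touching the image border are flagged
    ``is_border``; faces with fewer than 3 vertices, or smaller than
    ``min_face_area_px``, are dropped with a logged warning.
    """
    from skimage.measure import find_contours, label

    skel = np.asarray(skeleton, dtype=bool)
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 2)
    labels = label(~skel, connectivity=1)
    h, w = skel.shape

    # the field-of-view boundary may itself be traced by junction signal, in
    # which case clipped cells appear as ordinary enclosed faces; flag any
    # face that approaches the image edge as border
    m = BORDER_MARGIN_PX
    border_labels = (
        set(np.unique(labels[:m, :])) | set(np.unique(labels[-m:, :]))
        | set(np.unique(labels[:, :m])) | set(np.unique(labels[:, -m:]))
    )
    border_labels.discard(0)

    # assign each vertex to every face whose pixels appear in a small window
    face_vertices: dict[int, list[int]] = {}
    for vid, (r, c) in enumerate(vertices):
        r0 = max(int(round(r)) - VERTEX_ASSIGN_RADIUS, 0)
        r1 = min(int(round(r)) + VERTEX_ASSIGN_RADIUS + 1, h)
        c0 = max(int(round(c)) - VERTEX_ASSIGN_RADIUS, 0)
        c1 = min(int(round(c)) + VERTEX_ASSIGN_RADIUS + 1, w)
        for lab in np.unique(labels[r0:r1, c0:c1]):
            if lab != 0:
                face_vertices.setdefault(int(lab), []).append(vid)

    objects = ndimage.find_objects(labels)
    cells: list[CellPolygon] = []
    edge_faces: dict[frozenset, list[int]] = {}
    for lab, vids in sorted(face_vertices.items()):
        sl = objects[lab - 1]
        npix = int(np.sum(labels[sl] == lab))
        if npix < min_face_area_px:
            logger.warning("face %d dropped: %d px below minimum area", lab, npix)
            continue
        if len(set(vids)) < 3:
            logger.warning("face %d dropped: fewer than 3 vertices", lab)
            continue
        # order the face's vertices along its boundary contour
        pad = 1
        mask = np.zeros(
            (sl[0].stop - sl[0].start + 2 * pad, sl[1].stop - sl[1].start + 2 * pad)
        )
        mask[pad:-pad, pad:-pad] = labels[sl] == lab
        contours = find_contours(mask, 0.5)
        contour = max(contours, key=len)
        contour += np.array([sl[0].start - pad, sl[1].start - pad])
        tree = cKDTree(contour)
        vids = list(dict.fromkeys(vids))  # dedupe, keep insertion order
        _, order_idx = tree.query(vertices[vids])
        ordered = [v for _, v in sorted(zip(order_idx, vids))]
        # (row, col) px -> (x, y) μm
        pts = np.column_stack(
            [
                (vertices[ordered, 1] + 0.5) * pixel_size,
                (vertices[ordered, 0] + 0.5) * pixel_size,
            ]
        )
        try:
            cell = CellPolygon(
                cell_id=len(cells),
                vertices=pts,
                is_border=lab in border_labels,
            )
        except ValueError as exc:
            logger.warning("face %d dropped: %s", lab, exc)
            continue
        # recover vertex ids in the (possibly reversed) stored order
        cells.append(cell)
        cid = cell.cell_id
        for k in range(len(ordered)):
            e = frozenset((ordered[k], ordered[(k + 1) % len(ordered)]))
            if len(e) == 2:
                edge_faces.setdefault(e, []).append(cid)

    for faces in edge_faces.values():
        for i in range(len(faces)):
            for j in range(i + 1, len(faces)):
                cells[faces[i]].neighbor_ids.add(faces[j])
                cells[faces[j]].neighbor_ids.add(faces[i])

    return Monolayer(
        cells=cells,
        box=(w * pixel_size, h * pixel_size),
        pixel_size=pixel_size,
    )


def segment_image(
    image: np.ndarray,
    pixel_size: float,
    threshold_method="otsu",
    min_component_px: int = 10,
    min_face_area_px: int = 32,
) -> Monolayer:
    """Full pipeline: threshold + skeletonize, detect vertices, build polygons."""
    skel = skeletonize_junctions(image, threshold_method, min_component_px)
    verts = detect_vertices(skel)
    return build_polygons(skel, verts, pixel_size, min_face_area_px)
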