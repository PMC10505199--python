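"""Segmentation accuracy against ground truth.

Segmented cells are matched to ground-truth cells by mutual nearest
centroids; the match table feeds recovery rate, centroid error, relative
area error and a neighbour-relation F1 score (precision/recall of the
undirected adjacency among matched interior cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Monolayer


@dataclass
class SegmentationAccuracy:
    matches: pd.DataFrame
    recovery: float  # matched fraction of interior ground-truth cells
    median_centroid_error: float  # μm
    median_area_error: float  # relative
    neighbor_f1: float


def match_cells(
    truth: Monolayer, seg: Monolayer, max_dist: float | None = None
) -> pd.DataFrame:
    """Mutual-nearest-centroid matches between interior truth cells and
    segmented cells (any), within ``max_dist`` μm (default R_cc/2)."""
    t_cells = truth.interior_cells
    s_cells = seg.cells
    if not t_cells or not s_cells:
        return pd.DataFrame(columns=["truth_id", "seg_id", "centroid_error", "area_error"])
    if max_dist is None:
        max_dist = (truth.rcc or 16.0) / 2.0
    tc = np.array([c.centroid for c in t_cells])
    sc = np.array([c.centroid for c in s_cells])
    t_tree, s_tree = cKDTree(tc), cKDTree(sc)
    d_ts, near_s = s_tree.query(tc)
    _, near_t = t_tree.query(sc)
    rows = []
    for i, c in enumerate(t_cells):
        j = near_s[i]
        if d_ts[i] <= max_dist and near_t[j] == i:
            s = s_cells[j]
            rows.append(
                dict(
                    truth_id=c.cell_id,
                    seg_id=s.cell_id,
                    centroid_error=float(d_ts[i]),
                    area_error=abs(s.area - c.area) / c.area,
                )
            )
    return pd.DataFrame(rows)


def segmentation_accuracy(
    truth: Monolayer, seg: Monolayer, max_dist: float | None = None
) -> SegmentationAccuracy:
    matches = match_cells(truth, seg, max_dist)
    n_interior = len(truth.interior_cells)
    if matches.empty:
        return SegmentationAccuracy(matches, 0.0, np.inf, np.inf, 0.0)
    recovery = len(matches) / n_interior

    t2s = dict(zip(matches["truth_id"], matches["seg_id"]))
    truth_pairs = {
        (a, b)
        for a, b in truth.neighbor_pairs(interior_only=True)
        if a in t2s and b in t2s
    }
    seg_ids = set(t2s.values())
    s2t = {v: k for k, v in t2s.items()}
    seg_pairs = set()
    for a, b in seg.neighbor_pairs(interior_only=False):
        if a in seg_ids and b in seg_ids:
            seg_pairs.add(tuple(sorted((s2t[a], s2t[b]))))
    tp = len(truth_pairs & seg_pairs)
    fp = len(seg_pairs - truth_pairs)
    fn = len(truth_pairs - seg_pairs)
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if tp else 0.0
    return SegmentationAccuracy(
        matches=matches,
        recovery=float(recovery),
        median_centroid_error=float(matches["centroid_error"].median()),
        median_area_error=float(matches["area_error"].median()),
        neighbor_f1=float(f1),
    )
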