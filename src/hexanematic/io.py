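"""Reading and writing the pipeline's file formats.

Polygons travel as tidy CSV (cell_id, vertex_index, x_um, y_um) or as a
self-contained JSON document that also carries adjacency, border flags, box
size and pixel size (the lossless round-trip format).  Images are
single-channel TIFFs with the pixel size recorded in the ImageJ-style
metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellPolygon, Monolayer
from .shape import ShapeRecord


def write_polygons_csv(monolayer: Monolayer, path) -> None:
    rows = []
    for c in monolayer.cells:
        for k, (x, y) in enumerate(c.vertices):
            rows.append((c.cell_id, k, x, y))
    pd.DataFrame(rows, columns=["cell_id", "vertex_index", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_polygons_csv(path, box=None, pixel_size=None) -> Monolayer:
    """Polygons-only CSV; adjacency and border flags are not in this format,
    so neighbours are empty and the box defaults to the coordinate extent."""
    df = pd.read_csv(path)
    cells = []
    for cid, g in df.sort_values(["cell_id", "vertex_index"]).groupby("cell_id"):
        cells.append(
            CellPolygon(cell_id=int(cid), vertices=g[["x_um", "y_um"]].to_numpy())
        )
    if box is None:
        box = (float(df["x_um"].max()), float(df["y_um"].max()))
    return Monolayer(cells=cells, box=box, pixel_size=pixel_size)


def write_adjacency_csv(monolayer: Monolayer, path) -> None:
    pairs = monolayer.neighbor_pairs(interior_only=False)
    pd.DataFrame(pairs, columns=["cell_id_a", "cell_id_b"]).to_csv(path, index=False)


def write_monolayer_json(monolayer: Monolayer, path) -> None:
    doc = {
        "box": list(monolayer.box),
        "pixel_size": monolayer.pixel_size,
        "rcc": monolayer.rcc,
        "cells": [
            {
                "cell_id": c.cell_id,
                "vertices": np.asarray(c.vertices).tolist(),
                "neighbor_ids": sorted(c.neighbor_ids),
                "is_border": bool(c.is_border),
            }
            for c in monolayer.cells
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_monolayer_json(path) -> Monolayer:
    doc = json.loads(Path(path).read_text())
    cells = [
        CellPolygon(
            cell_id=c["cell_id"],
            vertices=np.asarray(c["vertices"], dtype=float),
            neighbor_ids=set(c["neighbor_ids"]),
            is_border=c["is_border"],
        )
        for c in doc["cells"]
    ]
    return Monolayer(
        cells=cells,
        box=tuple(doc["box"]),
        pixel_size=doc.get("pixel_size"),
        rcc=doc.get("rcc"),
    )


def write_tiff(image: np.ndarray, path, pixel_size: float) -> None:
    import tifffile

    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.float32),
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        metadata={"unit": "um", "pixel_size_um": pixel_size},
    )


def read_tiff(path, pixel_size: float | None = None) -> tuple[np.ndarray, float | None]:
    """Returns (image, pixel_size_um); an explicit ``pixel_size`` overrides
    whatever the metadata carries."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        image = tf.asarray()
        ps = pixel_size
        if ps is None:
            meta = tf.imagej_metadata or tf.shaped_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            ps = meta.get("pixel_size_um")
            if ps is None:
                res = tf.pages[0].tags.get("XResolution")
                if res is not None:
                    num, den = res.value
                    if num:
                        ps = den / num
    return image, ps


def shape_records_frame(records: dict[int, ShapeRecord]) -> pd.DataFrame:
    """Per-cell table: p0 plus re/im/abs/orientation of gamma_2 and gamma_6."""
    rows = []
    for r in records.values():
        row = {"cell_id": r.cell_id, "p0": r.p0}
        for p, g in r.gamma.items():
            row[f"re_gamma{p}"] = g.real
            row[f"im_gamma{p}"] = g.imag
            row[f"abs_gamma{p}"] = abs(g)
            row[f"theta{p}"] = r.orientation[p]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
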