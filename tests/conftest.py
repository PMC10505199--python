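import logging

import numpy as np
import pytest

import hexanematic as hx

logging.getLogger("hexanematic").setLevel(logging.ERROR)


def regular_polygon(n: int, radius: float = 1.0, rotation: float = 0.0,
                    center=(0.0, 0.0)) -> hx.CellPolygon:
    ang = rotation + 2.0 * np.pi * np.arange(n) / n
    verts = np.column_stack([
        center[0] + radius * np.cos(ang),
        center[1] + radius * np.sin(ang),
    ])
    return hx.CellPolygon(cell_id=0, vertices=verts)


def star_polygon(rng: np.random.Generator, n: int | None = None) -> hx.CellPolygon:
    """Random simple (star-shaped) polygon: sorted angles, random radii."""
    if n is None:
        n = int(rng.integers(3, 13))
    ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    # keep angles distinct so edges cannot degenerate
    ang += np.linspace(0.0, 1e-3, n)
    rad = rng.uniform(0.2, 1.0, n)
    verts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    verts += rng.uniform(-5.0, 5.0, 2)
    return hx.CellPolygon(cell_id=0, vertices=verts)


@pytest.fixture(scope="session")
def hex_lattice() -> hx.Monolayer:
    """Perfect triangular-lattice monolayer: interior cells are regular hexagons."""
    cfg = hx.GeneratorConfig(box_width=160, box_height=160, target_rcc=16,
                             jitter=0.0, seed=0)
    ml = hx.generate_monolayer(cfg)
    hx.mean_cell_cell_distance(ml)
    return ml


@pytest.fixture(scope="session")
def jittered_ml() -> hx.Monolayer:
    cfg = hx.GeneratorConfig(box_width=208, box_height=208, target_rcc=16,
                             jitter=0.3, seed=1)
    ml = hx.generate_monolayer(cfg)
    hx.mean_cell_cell_distance(ml)
    return ml


@pytest.fixture(scope="session")
def rendered_fixture():
    """Study-condition monolayer, its noisy junction image, and the config.

    Noise sd is 10% of the nominal ridge intensity (1.0).
    """
    cfg = hx.study_config(16.2, elongation=1.2, seed=1, noise_sd=0.1)
    ml = hx.generate_monolayer(cfg)
    hx.mean_cell_cell_distance(ml)
    img = hx.render_junction_image(ml, cfg)
    return ml, img, cfg


@pytest.fixture(scope="session")
def toy_monolayer_with_records():
    """Small random monolayer with synthetic complex shape values attached."""
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 100, size=(24, 2))
    ml = hx.tessellate(pts, (100.0, 100.0))
    ml.rcc = 20.0
    records = {}
    for c in ml.interior_cells:
        records[c.cell_id] = hx.ShapeRecord(
            cell_id=c.cell_id, p0=4.0,
            gamma={2: complex(*rng.normal(0, 0.4, 2)),
                   6: complex(*rng.normal(0, 0.4, 2))},
            orientation={2: 0.0, 6: 0.0},
        )
    return ml, records


@pytest.fixture(scope="session")
def study_ensemble():
    """Summary of the study grid (3 densities x 4 elongations x 5 seeds,
    ~200 cells each): per-fixture single-cell averages and the pooled
    hexanematic crossover per condition."""
    out = {}
    for rcc in hx.STUDY_RCC_UM:
        for e in hx.STUDY_ELONGATIONS:
            profs, g6s, g2s, p0s = [], [], [], []
            for seed in range(5):
                cfg = hx.study_config(rcc, elongation=e, seed=seed)
                ml = hx.generate_monolayer(cfg)
                rc = hx.mean_cell_cell_distance(ml)
                recs = hx.compute_shape_records(ml)
                g6s.append(hx.ensemble_average(recs, 6))
                g2s.append(hx.ensemble_average(recs, 2))
                p0s.append(float(np.mean([r.p0 for r in recs.values()])))
                radii, p6, p2, _ = hx.hexanematic_profile(ml, recs)
                profs.append((radii, p6, p2, rc))
            cross = hx.pooled_crossover(profs)
            out[(rcc, e)] = dict(g6=g6s, g2=g2s, p0=p0s, r_cross=cross.r_cross,
                                 regime=cross.regime)
    return out
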