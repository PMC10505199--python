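"""Topological defect detection via plaquette winding numbers."""

import math

import numpy as np
import pytest

import hexanematic as hx
from hexanematic.coarse import CoarseField, Grid
from hexanematic.defects import find_defects, orientation_field, winding_number


def defect_theta(x, y, p, charge_sign=1, center=(0.0, 0.0)):
    """Analytic p-atic director with a single +-1/p defect at ``center``."""
    return charge_sign * np.arctan2(y - center[1], x - center[0]) / p


def field_from_theta(theta_grid, p, grid):
    values = np.exp(1j * p * theta_grid)
    return CoarseField(p=p, rcc=1.0, radii=np.array([1.0]), grid=grid,
                       values=values[None, :, :])


def square_grid(n, spacing=1.0, origin=(0.0, 0.0)):
    return Grid(origin=origin, spacing=spacing, nx=n, ny=n)


class TestOrientationField:
    def test_constant_field(self):
        theta = orientation_field(np.full((4, 4), np.exp(1j * np.pi / 2)), 2)
        assert np.allclose(theta, np.pi / 4)

    def test_global_rotation_shifts_phase(self):
        rng = np.random.default_rng(0)
        vals = np.exp(1j * rng.uniform(0, 2 * np.pi, (5, 5)))
        alpha = 0.3
        t0 = orientation_field(vals, 2)
        t1 = orientation_field(vals * np.exp(2j * alpha), 2)
        diff = (t1 - t0 - alpha) % np.pi
        assert np.allclose(np.minimum(diff, np.pi - diff), 0.0, atol=1e-12)

    def test_zero_value_undefined(self):
        vals = np.ones((3, 3), dtype=complex)
        vals[1, 1] = 0.0
        with pytest.warns(UserWarning):
            theta = orientation_field(vals, 6)
        assert np.isnan(theta[1, 1])

    def test_range(self):
        rng = np.random.default_rng(1)
        vals = np.exp(1j * rng.uniform(-10, 10, (6, 6)))
        for p in (2, 6):
            theta = orientation_field(vals, p)
            assert np.all((theta >= 0) & (theta < 2 * np.pi / p))


class TestWindingNumber:
    def test_uniform_is_zero(self):
        assert winding_number([0.3, 0.3, 0.3, 0.3], 2) == 0.0

    def corners(self):
        # unit plaquette corners around the origin, counterclockwise
        return [(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]

    def test_plus_half_nematic(self):
        th = [defect_theta(x, y, 2) for x, y in self.corners()]
        assert winding_number(th, 2) == pytest.approx(0.5)

    def test_minus_sixth_hexatic(self):
        th = [defect_theta(x, y, 6, charge_sign=-1) for x, y in self.corners()]
        assert winding_number(th, 6) == pytest.approx(-1.0 / 6.0)

    def test_conjugate_field_flips_charge(self):
        th = [defect_theta(x, y, 2) for x, y in self.corners()]
        assert winding_number([-t for t in th], 2) == pytest.approx(-0.5)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            winding_number([0.0, np.nan, 0.0, 0.0], 2)

    @pytest.mark.parametrize("p,sign", [(2, 1), (2, -1), (6, 1), (6, -1)])
    def test_matches_dense_contour_integration(self, p, sign):
        """4-corner winding equals a 64-point contour integral of the same
        analytic defect field."""
        th4 = [defect_theta(x, y, p, sign) for x, y in self.corners()]
        s4 = winding_number(th4, p)
        # dense sampling along the plaquette contour
        t = np.linspace(0, 4, 256, endpoint=False)
        cs = self.corners() + [self.corners()[0]]
        pts = []
        for u in t:
            i = int(u)
            f = u - i
            a, b = np.array(cs[i]), np.array(cs[i + 1])
            pts.append(a + f * (b - a))
        th = np.array([defect_theta(x, y, p, sign) for x, y in pts])
        d = np.diff(np.append(th, th[0]))
        half = math.pi / p
        wrapped = half - np.mod(half - d, 2 * half)
        s_dense = wrapped.sum() / (2 * math.pi)
        assert s4 == pytest.approx(s_dense, abs=1e-9)


class TestFindDefects:
    def test_smooth_field_empty(self):
        grid = square_grid(10)
        xx, yy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        theta = 0.01 * xx + 0.02 * yy
        ds = find_defects(field_from_theta(theta, 2, grid), n_cells=100)
        assert len(ds.charges) == 0
        assert ds.density_per_100 == 0.0

    def test_seeded_pair_detected_and_neutral(self):
        grid = square_grid(20)
        xx, yy = np.meshgrid(np.arange(20.0), np.arange(20.0))
        c1, c2 = (5.5, 9.5), (14.5, 9.5)
        theta = (np.arctan2(yy - c1[1], xx - c1[0])
                 - np.arctan2(yy - c2[1], xx - c2[0])) / 2.0
        ds = find_defects(field_from_theta(theta, 2, grid), n_cells=100)
        assert len(ds.charges) == 2
        assert sorted(ds.charges) == [-0.5, 0.5]
        assert ds.total_charge == 0.0
        # positions within one plaquette of the seeded cores
        for center in (c1, c2):
            dmin = np.min(np.linalg.norm(ds.positions - center, axis=1))
            assert dmin <= math.sqrt(2.0)

    def test_charges_quantized_on_synthetic_monolayer(self):
        cfg = hx.study_config(16.2, elongation=1.2, seed=0)
        ml = hx.generate_monolayer(cfg)
        hx.mean_cell_cell_distance(ml)
        records = hx.compute_shape_records(ml)
        field = hx.coarse_gamma(ml, records, 6, radii=[ml.rcc])
        ds = find_defects(field, n_cells=len(ml.interior_cells))
        assert len(ds.charges) > 0
        steps = ds.charges * 6
        assert np.allclose(steps, np.round(steps), atol=1e-9)

    def test_pair_annihilates_under_coarse_graining(self):
        """A +-1/2 pair separated by d disappears from the coarse field once
        R substantially exceeds d."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (400, 2))
        ml = hx.tessellate(pts, (100.0, 100.0))
        ml.rcc = 5.0
        c1, c2 = np.array([40.0, 50.0]), np.array([60.0, 50.0])
        records = {}
        for c in ml.interior_cells:
            x, y = c.centroid
            th = (math.atan2(y - c1[1], x - c1[0])
                  - math.atan2(y - c2[1], x - c2[0])) / 2.0
            records[c.cell_id] = hx.ShapeRecord(c.cell_id, 4.0,
                                                {2: np.exp(2j * th)}, {2: th})
        counts = []
        for R in (4.0, 60.0):
            field = hx.coarse_gamma(ml, records, 2, radii=[R], fov=100.0)
            ds = find_defects(field, n_cells=len(ml.interior_cells))
            counts.append(len(ds.charges))
        assert counts[0] >= 2
        assert counts[-1] == 0


class TestDensityVsRadius:
    def test_defect_free_lattice_zero_everywhere(self, hex_lattice):
        records = hx.compute_shape_records(hex_lattice)
        table, at_cross = hx.defect_density_vs_radius(hex_lattice, records, p=6)
        assert (table["density_per_100"] == 0).all()
        assert at_cross["density_per_100"] is None

    def test_at_crossover_uses_nearest_ladder_radius(self, hex_lattice):
        records = hx.compute_shape_records(hex_lattice)
        table, at_cross = hx.defect_density_vs_radius(
            hex_lattice, records, p=6, r_cross_norm=1.1)
        k = np.argmin(np.abs(table["radius_norm"].values - 1.1))
        assert at_cross["radius"] == pytest.approx(table["radius"].iloc[k])

    def test_density_independent_of_system_size(self):
        """Twice the cells at the same statistics: per-100-cells density is
        stable (the defect count scales with the cell count)."""
        def density(cells, seed):
            # isotropic, jitter-only disorder: self-averaging defect
            # statistics that are identical across system sizes
            base = hx.study_config(16.2, seed=seed, cells=cells)
            cfg = hx.GeneratorConfig(**{**base.to_dict(), "elongation": 1.0,
                                        "jitter": 0.5, "warp": 0.0})
            ml = hx.generate_monolayer(cfg)
            hx.mean_cell_cell_distance(ml)
            records = hx.compute_shape_records(ml)
            # analyse the full box so defect count and cell count scale together
            table, _ = hx.defect_density_vs_radius(ml, records, p=2, fov=ml.box[0])
            return table["density_per_100"].values[:3].mean()

        d1 = np.mean([density(150, s) for s in range(4)])
        d2 = np.mean([density(300, s) for s in range(4)])
        assert d2 == pytest.approx(d1, rel=0.2)
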