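import numpy as np
import pytest

from topplekit import (BilayerSpec, Frame, MembraneMapper, Selection,
                       assign_leaflets, default_topology, fit_leaflet_surface,
                       make_bilayer_trajectory, mean_curvature_map,
                       protein_footprint, thickness_map)
from topplekit.membrane import SurfaceFit, _monomial_exponents

BOX = [20.0, 20.0, 10.0]


def _lipid_frame(lipid_specs, box=BOX):
    """Build a frame from (resname, [(bead_name, x, y, z), ...]) lipid specs."""
    indices, names, resnames, resids, positions = [], [], [], [], []
    pid = 1
    for rid, (resname, beads) in enumerate(lipid_specs, start=1):
        for bead, x, y, z in beads:
            indices.append(pid)
            names.append(bead)
            resnames.append(resname)
            resids.append(rid)
            positions.append((x, y, z))
            pid += 1
    return Frame(indices, names, resnames, resids, [""] * len(indices),
                 np.asarray(positions), box)


class TestLeafletAssignment:
    def test_flat_bilayer_split(self):
        lipids = [("POPE", [("PO4", i * 1.0, 0.0, 7.0)]) for i in range(6)]
        lipids += [("POPE", [("PO4", i * 1.0, 0.0, 3.0)]) for i in range(6)]
        a = assign_leaflets(_lipid_frame(lipids), default_topology())
        labels = list(a.labels.values())
        assert labels.count("upper") == 6 and labels.count("lower") == 6
        assert "excluded" not in labels

    def test_midplane_lipid_excluded(self):
        lipids = [("POPE", [("PO4", 0, 0, 7.0)]), ("POPE", [("PO4", 1, 0, 3.0)]),
                  ("POPE", [("PO4", 2, 0, 5.1)])]
        a = assign_leaflets(_lipid_frame(lipids), default_topology())
        assert a.labels[(3, "POPE")] == "excluded"

    def test_cardiolipin_phosphates_averaged(self):
        lipids = [("POPE", [("PO4", 0, 0, 7.0)]), ("POPE", [("PO4", 1, 0, 3.0)]),
                  ("CL", [("PO41", 2, 0, 6.9), ("PO42", 2.3, 0, 7.1)])]
        a = assign_leaflets(_lipid_frame(lipids), default_topology())
        assert a.labels[(3, "CL")] == "upper"

    def test_no_phosphates_matched_names_topology(self):
        lipids = [("POPE", [("XX", 0, 0, 7.0)]), ("POPE", [("XX", 1, 0, 3.0)])]
        with pytest.raises(ValueError, match="phosphate"):
            assign_leaflets(_lipid_frame(lipids), default_topology())


class TestSurfaceFit:
    def test_plane_gives_constant_fit(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, size=(50, 2))
        pts = np.column_stack([xy, np.full(50, 2.0)])
        fit = fit_leaflet_surface(pts)
        assert fit.fit_rms == pytest.approx(0.0, abs=1e-9)
        assert fit.evaluate(3.0, 4.0) == pytest.approx(2.0, abs=1e-8)

    def test_paraboloid_coefficients_recovered(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-5, 5, size=(400, 2))
        z = 2.0 + 0.05 * xy[:, 0] ** 2 + 0.05 * xy[:, 1] ** 2 + rng.normal(0, 0.05, 400)
        fit = fit_leaflet_surface(np.column_stack([xy, z]))
        grid = np.linspace(-4, 4, 9)
        X, Y = np.meshgrid(grid, grid)
        truth = 2.0 + 0.05 * X**2 + 0.05 * Y**2
        assert np.max(np.abs(fit.evaluate(X, Y) - truth)) < 0.05

    def test_too_few_points_rejected(self):
        pts = np.random.default_rng(2).uniform(0, 5, size=(10, 3))
        with pytest.raises(ValueError, match="at least 15"):
            fit_leaflet_surface(pts)

    def test_collinear_points_rejected(self):
        x = np.linspace(0, 5, 30)
        pts = np.column_stack([x, np.zeros(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_leaflet_surface(pts)


def _flat_fit(z0, leaflet="upper", half=10.0):
    exps = _monomial_exponents(4)
    coef = np.zeros(len(exps))
    coef[exps.index((0, 0))] = z0
    return SurfaceFit(leaflet=leaflet, coefficients=coef, degree=4, origin=(0.0, 0.0),
                      fit_rms=0.0, domain=((-half, half), (-half, half)), exponents=exps)


def _poly_fit(coef_map, leaflet="upper", half=10.0):
    exps = _monomial_exponents(4)
    coef = np.zeros(len(exps))
    for key, val in coef_map.items():
        coef[exps.index(key)] = val
    return SurfaceFit(leaflet=leaflet, coefficients=coef, degree=4, origin=(0.0, 0.0),
                      fit_rms=0.0, domain=((-half, half), (-half, half)), exponents=exps)


EDGES = np.linspace(-5, 5, 21)


class TestThicknessMap:
    def test_flat_leaflets(self):
        gm = thickness_map(_flat_fit(2.0), _flat_fit(-2.0, "lower"), EDGES, EDGES)
        assert np.allclose(gm.values, 4.0)

    def test_mirror_symmetry_equals_twice_upper(self):
        up = _poly_fit({(0, 0): 2.0, (2, 0): 0.01, (0, 2): -0.02, (1, 1): 0.005})
        low = SurfaceFit(leaflet="lower", coefficients=-up.coefficients, degree=4,
                         origin=(0.0, 0.0), fit_rms=0.0, domain=up.domain,
                         exponents=up.exponents)
        gm = thickness_map(up, low, EDGES, EDGES)
        cx, cy = gm.cell_centers
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        assert gm.values == pytest.approx(2.0 * up.evaluate(X, Y))

    def test_inverted_leaflets_warn_and_report_negative(self, caplog):
        with caplog.at_level("WARNING"):
            gm = thickness_map(_flat_fit(-2.0), _flat_fit(2.0, "lower"), EDGES, EDGES)
        assert np.all(gm.values < 0)
        assert "negative" in caplog.text

    def test_grid_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            thickness_map(_flat_fit(2.0, half=3.0), _flat_fit(-2.0, "lower"),
                          EDGES, EDGES)


class TestMeanCurvature:
    def test_flat_surface_zero(self):
        gm = mean_curvature_map(_flat_fit(2.0), EDGES, EDGES)
        assert np.allclose(gm.values, 0.0)

    def test_paraboloid_analytic_value(self):
        fit = _poly_fit({(2, 0): 0.05, (0, 2): 0.05})
        assert fit.mean_curvature(0.0, 0.0) == pytest.approx(0.1)

    def test_offset_invariance_and_reflection_antisymmetry(self):
        fit = _poly_fit({(0, 0): 1.0, (2, 0): 0.03, (0, 2): 0.02, (1, 1): 0.01,
                         (3, 0): 0.002, (0, 4): 0.001})
        shifted = SurfaceFit("upper", fit.coefficients.copy(), 4, (0.0, 0.0), 0.0,
                             fit.domain, fit.exponents)
        shifted.coefficients[fit.exponents.index((0, 0))] += 5.0
        reflected = SurfaceFit("upper", -fit.coefficients, 4, (0.0, 0.0), 0.0,
                               fit.domain, fit.exponents)
        x = np.linspace(-4, 4, 11)
        X, Y = np.meshgrid(x, x)
        assert shifted.mean_curvature(X, Y) == pytest.approx(fit.mean_curvature(X, Y))
        assert reflected.mean_curvature(X, Y) == pytest.approx(-fit.mean_curvature(X, Y))

    def test_analytic_matches_finite_difference(self):
        # independent oracle: 2nd-order central differences of the evaluated surface
        rng = np.random.default_rng(7)
        x = np.linspace(-3, 3, 13)
        X, Y = np.meshgrid(x, x)
        h = 1e-3
        for _ in range(5):
            coef = {}
            for i in range(5):
                for j in range(5 - i):
                    coef[(i, j)] = rng.uniform(-0.5, 0.5) / (4.0 ** (i + j))
            fit = _poly_fit(coef)
            f = fit.evaluate
            zx = (f(X + h, Y) - f(X - h, Y)) / (2 * h)
            zy = (f(X, Y + h) - f(X, Y - h)) / (2 * h)
            zxx = (f(X + h, Y) - 2 * f(X, Y) + f(X - h, Y)) / h**2
            zyy = (f(X, Y + h) - 2 * f(X, Y) + f(X, Y - h)) / h**2
            zxy = (f(X + h, Y + h) - f(X + h, Y - h) - f(X - h, Y + h)
                   + f(X - h, Y - h)) / (4 * h**2)
            H_fd = ((1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy) \
                / (2 * (1 + zx**2 + zy**2) ** 1.5)
            assert np.max(np.abs(fit.mean_curvature(X, Y) - H_fd)) < 1e-4

    def test_sphere_cap_cloud(self):
        # bowl-shaped cap of a radius-10 sphere: H = +1/R at the apex
        R = 10.0
        rng = np.random.default_rng(5)
        xy = rng.uniform(-2.5, 2.5, size=(800, 2))
        r2 = (xy**2).sum(axis=1)
        z = R - np.sqrt(R**2 - r2)
        fit = fit_leaflet_surface(np.column_stack([xy, z]))
        H = fit.mean_curvature(np.array([0.0, 0.2, -0.2]), np.array([0.0, 0.1, 0.0]))
        assert H == pytest.approx(0.1, rel=0.05)


class TestProteinFootprint:
    def test_no_protein_empty_mask(self, simple_frame):
        edges = np.linspace(0, 10, 51)
        mask = protein_footprint(simple_frame, None, edges, edges)
        assert not mask.any()

    def test_single_particle_masks_disc(self):
        n = 1
        fr = Frame([1], ["P1"], ["PRT"], [1], ["A"],
                   np.array([[5.0, 5.0, 5.0]]), [10.0, 10.0, 10.0])
        edges = np.arange(0.0, 10.0 + 1e-9, 0.2)
        mask = protein_footprint(fr, Selection("p", [1]), edges, edges, pad=0.3)
        # brute-force cell enumeration
        cx = 0.5 * (edges[:-1] + edges[1:])
        X, Y = np.meshgrid(cx, cx, indexing="ij")
        expected = (X - 5.0) ** 2 + (Y - 5.0) ** 2 <= 0.3**2 + 1e-12
        assert np.array_equal(mask, expected)
        assert mask.sum() == expected.sum() > 0

    def test_protein_covering_grid_fails_downstream(self):
        spec = BilayerSpec(box=(6.0, 6.0, 10.0), n_lipids_per_leaflet=60, seed=0)
        frames, topo = make_bilayer_trajectory(spec, n_frames=1)
        # a fake protein particle blanket: select every particle, huge pad
        sel = Selection("all", frames[0].indices)
        mapper = MembraneMapper(grid_spacing=0.5, footprint_pad=20.0)
        with pytest.raises(ValueError, match="whole grid"):
            mapper.fit(frames, topo, protein_sel=sel)


class TestMembraneMapper:
    def test_flat_bilayer_recovers_thickness(self):
        spec = BilayerSpec(box=(12.0, 12.0, 10.0), n_lipids_per_leaflet=230, seed=8)
        frames, topo = make_bilayer_trajectory(spec, n_frames=5)
        mapper = MembraneMapper(grid_spacing=0.6).fit(frames, topo)
        vals = mapper.thickness_.values
        assert np.nanmax(np.abs(vals - 4.0)) < 0.1
        assert np.nanmax(np.abs(mapper.curvature_upper_.values)) < 0.05

    def test_global_mode_matches_local_on_flat_patch(self):
        spec = BilayerSpec(box=(10.0, 10.0, 10.0), n_lipids_per_leaflet=160, seed=9)
        frames, topo = make_bilayer_trajectory(spec, n_frames=3)
        loc = MembraneMapper(grid_spacing=1.0, mode="local").fit(frames, topo)
        glo = MembraneMapper(grid_spacing=1.0, mode="global").fit(frames, topo)
        assert np.nanmax(np.abs(loc.thickness_.values - glo.thickness_.values)) < 0.15
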