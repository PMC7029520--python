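"""Volume-conductor solver vs closed-form oracles, and field services.

The point-source solutions in unbounded homogeneous media are imposed as
Dirichlet data on the outer boundary, so the discrete solution must match
the closed form everywhere up to discretization error.
"""

import numpy as np
import pytest

from enm.geometry import cross_section_from_circles
from enm.volume_conductor import (
    SIGMA,
    GridSpec,
    LeadField,
    LeadFieldSolver,
    LinearSystem,
    SolverError,
    build_conductivity_map,
    sample_at_nodes,
    superpose,
)

I_TEST = 1e-6  # 1 uA


def analytic_point_source(sig_t, sig_z, xyz_m):
    """V for unit current at the origin in an unbounded anisotropic medium."""
    x, y, z = xyz_m[..., 0], xyz_m[..., 1], xyz_m[..., 2]
    rt = np.sqrt((x**2 + y**2) / sig_t + z**2 / sig_z)
    return 1.0 / (4 * np.pi * np.sqrt(sig_t * sig_t * sig_z) * np.maximum(rt, 1e-12))


def _homogeneous_solution(sig_t, sig_z, h_fine=0.13):
    """Solve a manually-sourced homogeneous problem with analytic boundary data.

    Near-source cells are kept cubic (aspect ratio distorts the discrete
    Green's function) via a refinement box around the origin.
    """
    cs = cross_section_from_circles((3.0, 2.0), [(0.6, 0.0, 0.8)])
    cs.extrusion_length = 20.0
    cmap = build_conductivity_map(
        cs, [], GridSpec(h_plane=0.25, h_axial=0.25, h_max=1.4, growth=0.45),
        symmetric_z=False,
        extra_fine=((0.0, 0.0, 0.0), 1.0, h_fine),
    )
    st = np.full(cmap.shape, sig_t)
    sz = np.full(cmap.shape, sig_z)
    cx, cy, cz = cmap.centers
    i0 = int(np.argmin(np.abs(cx)))
    j0 = int(np.argmin(np.abs(cy)))
    k0 = int(np.argmin(np.abs(cz)))
    src_mm = np.array([cx[i0], cy[j0], cz[k0]])

    def boundary(X, Y, Z):
        pts = (np.stack([X, Y, Z], axis=-1) - src_mm) * 1e-3
        return analytic_point_source(sig_t, sig_z, pts)

    system = LinearSystem(cmap, sigma_override=(st, sz), boundary_values=boundary)
    rhs = np.zeros(system.n)
    rhs[system.idx[i0, j0, k0]] = 1.0
    x = system.solve(rhs)
    vals = np.zeros(cmap.shape)
    vals[system.active] = x
    return cmap, vals, src_mm, (i0, j0, k0)


class TestPointSourceOracles:
    def test_isotropic_saline_point_source(self):
        """V = I / (4 pi sigma r): 39.8 uV at 1 mm for 1 uA in 2 S/m."""
        sig = SIGMA["saline"]
        cmap, vals, src, _ = _homogeneous_solution(sig, sig)
        cx, cy, cz = cmap.centers
        for r_mm in (0.5, 1.0, 2.0, 4.0):
            j = int(np.argmin(np.abs(cy - (src[1] + r_mm))))
            i = int(np.argmin(np.abs(cx - src[0])))
            k = int(np.argmin(np.abs(cz - src[2])))
            probe = np.array([cx[i], cy[j], cz[k]])
            expected = analytic_point_source(sig, sig, (probe - src) * 1e-3) * I_TEST
            got = vals[i, j, k] * I_TEST
            assert got == pytest.approx(expected, rel=0.10)
        # the headline number: ~39.8 uV per uA at 1 mm
        j = int(np.argmin(np.abs(cy - (src[1] + 1.0))))
        i = int(np.argmin(np.abs(cx - src[0])))
        k = int(np.argmin(np.abs(cz - src[2])))
        assert vals[i, j, k] * I_TEST == pytest.approx(39.8e-6, rel=0.10)

    def test_anisotropic_point_source_elongated_along_z(self):
        # endoneurium-like tensor; along z the scaled source distance shrinks
        # by sqrt(sig_t/sig_z), so the near probe needs a finer grid
        sig_t, sig_z = SIGMA["endoneurium_t"], SIGMA["endoneurium_l"]
        cmap, vals, src, _ = _homogeneous_solution(sig_t, sig_z, h_fine=0.09)
        cx, cy, cz = cmap.centers
        i = int(np.argmin(np.abs(cx - src[0])))
        j = int(np.argmin(np.abs(cy - src[1])))
        k0 = int(np.argmin(np.abs(cz - src[2])))
        for r_mm in (0.5, 1.0, 2.0):
            jr = int(np.argmin(np.abs(cy - (src[1] + r_mm))))
            kr = int(np.argmin(np.abs(cz - (src[2] + r_mm))))
            for idx in ((i, jr, k0), (i, j, kr)):
                probe = np.array([cx[idx[0]], cy[idx[1]], cz[idx[2]]])
                expected = analytic_point_source(sig_t, sig_z, (probe - src) * 1e-3)
                assert vals[idx] == pytest.approx(expected, rel=0.10)
        # equipotentials stretch along z: V at z-offset r exceeds V at y-offset r
        jr = int(np.argmin(np.abs(cy - (src[1] + 2.0))))
        kr = int(np.argmin(np.abs(cz - (src[2] + 2.0))))
        assert vals[i, j, kr] > 1.5 * vals[i, jr, k0]

    def test_grid_refinement_changes_potentials_mildly(self):
        from scipy.interpolate import RegularGridInterpolator

        sig = SIGMA["saline"]
        sols = {}
        for h in (0.2, 0.1):
            cmap, vals, src, _ = _homogeneous_solution(sig, sig, h_fine=h)
            interp = RegularGridInterpolator(cmap.centers, vals)
            sols[h] = (interp, src)
        # identical physical probes inside the refined box
        for r_mm in (0.6, 1.0, 1.4):
            probes = []
            for h in (0.2, 0.1):
                interp, src = sols[h]
                probes.append(float(interp([src + np.array([0.0, r_mm, 0.0])])[0]))
            assert probes[0] == pytest.approx(probes[1], rel=0.05)


class TestLeadFieldServices:
    def test_linearity_and_current_scaling(self, toy_time_setup):
        lf = toy_time_setup["fields"][(0, 2)]
        p = np.array([[0.5, 0.4, 0.2]])
        assert lf.at(p, 2e-6) == pytest.approx(2 * lf.at(p, 1e-6), rel=1e-12)

    def test_resolving_doubled_source_doubles_potential(self, toy_time_setup):
        cmap = toy_time_setup["cmap"]
        solver = LeadFieldSolver(cmap)
        sysm = solver.system
        rhs = np.zeros(sysm.n)
        for (i, j, k, frac) in cmap.sources[(0, 2)]:
            rhs[sysm.idx[i, j, k]] += frac * (0.5 if cmap.symmetric_z else 1.0)
        x1 = sysm.solve(rhs)
        x2 = sysm.solve(2 * rhs)
        assert np.abs(x2 - 2 * x1).max() <= 1e-6 * np.abs(x1).max()

    def test_superposition_identity_and_cancellation(self, toy_time_setup):
        lf = toy_time_setup["fields"][(0, 1)]
        pts = np.array([[0.3, 0.3, 0.0], [1.0, -0.5, 1.0]])
        same = superpose([lf], [1.0])
        assert same.at(pts, 1e-6) == pytest.approx(lf.at(pts, 1e-6), rel=1e-12)
        zero = superpose([lf, lf], [1.0, -1.0])
        assert np.abs(zero.at(pts, 1e-6)).max() < 1e-15

    def test_bipolar_midpoint_weaker_than_monopolar(self, toy_time_setup):
        fields = toy_time_setup["fields"]
        # central same-face pair: symmetric tissue environment
        a, b = fields[(0, 2)], fields[(0, 3)]
        pa = toy_time_setup["placements"][0].as_global_positions()
        mid = (pa[2] + pa[3]) / 2.0
        mid[1] += 0.3  # just off the insulating ribbon
        bi = superpose([a, b], [1.0, -1.0])
        assert abs(bi.at([mid], 1e-6)[0]) < abs(a.at([mid], 1e-6)[0])
        assert abs(bi.at([mid], 1e-6)[0]) < abs(b.at([mid], 1e-6)[0])

    def test_mismatched_domains_rejected(self, toy_time_setup):
        lf = toy_time_setup["fields"][(0, 0)]
        other = LeadField(
            as_key=(9, 9),
            faces_x=lf.faces_x, faces_y=lf.faces_y, faces_z=lf.faces_z,
            values=lf.values, signature=("different",),
        )
        with pytest.raises(SolverError, match="same conductivity map"):
            superpose([lf, other], [1, -1])

    def test_grounded_boundary_and_monotone_decay(self, toy_time_setup):
        lf = toy_time_setup["fields"][(0, 2)]
        src = toy_time_setup["placements"][0].as_global_positions()[2]
        zs = np.array([0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
        pts = np.column_stack([np.full_like(zs, src[0]), np.full_like(zs, src[1] + 0.2), zs])
        v = np.abs(lf.at(pts, 1e-6))
        assert np.all(np.diff(v) < 0)
        edge = np.abs(lf.at([[0.0, 0.0, lf.faces_z[-1] - 0.3]], 1e-6))[0]
        assert edge < 0.02 * v[0]


class TestInterpolation:
    def _linear_field(self):
        fx = np.linspace(0, 1, 5)
        fy = np.linspace(0, 2, 6)
        fz = np.linspace(0, 3, 7)
        cx, cy, cz = 0.5 * (fx[1:] + fx[:-1]), 0.5 * (fy[1:] + fy[:-1]), 0.5 * (fz[1:] + fz[:-1])
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        vals = 2.0 * X - 3.0 * Y + 0.5 * Z
        return LeadField(as_key=(0, 0), faces_x=fx, faces_y=fy, faces_z=fz, values=vals), (cx, cy, cz)

    def test_grid_vertex_identity(self):
        lf, (cx, cy, cz) = self._linear_field()
        p = np.array([[cx[2], cy[3], cz[4]]])
        assert lf.at(p)[0] == pytest.approx(2 * cx[2] - 3 * cy[3] + 0.5 * cz[4], rel=1e-12)

    def test_linear_reproduction_at_cell_center(self):
        lf, _ = self._linear_field()
        p = np.array([[0.5, 1.0, 1.5]])
        assert sample_at_nodes(lf, p)[0] == pytest.approx(2 * 0.5 - 3 * 1.0 + 0.5 * 1.5, rel=1e-12)

    def test_out_of_domain_node_rejected(self):
        lf, _ = self._linear_field()
        with pytest.raises(SolverError, match="index 1"):
            lf.at(np.array([[0.5, 1.0, 1.5], [9.0, 0.0, 0.0]]))


class TestConductivityMap:
    def test_tissue_classification(self, toy_time_setup):
        cmap = toy_time_setup["cmap"]
        cs = toy_time_setup["cs"]
        c = cs.fascicles[2].centroid
        assert cmap.tissue_tensor(c[0], c[1]) == pytest.approx((0.0826, 0.0826, 0.571))
        assert cmap.tissue_tensor(0.0, 3.6) == pytest.approx((2.0, 2.0, 2.0))  # saline
        assert cmap.classify_point(0.5, 0.05, 0.0) == "substrate"  # on the ribbon
        assert cmap.tissue_tensor(0.5, 0.05, 0.0)[0] == pytest.approx(6.67e-14)

    def test_perineurium_shields_fascicle_interior(self, toy_nerve):
        from enm.electrodes import Placement, build_time

        pl = Placement(electrode=build_time(12, "distal"), insertion_point=(0.0, 0.05))
        grid = GridSpec(h_plane=0.25, h_axial=0.4, h_max=2.4, growth=0.5)
        cmap = build_conductivity_map(toy_nerve, [pl], grid)
        shielded = LeadFieldSolver(cmap).solve_as((0, 4))
        cmap2 = build_conductivity_map(toy_nerve, [pl], grid)
        cmap2.film_x[:] = 0.0
        cmap2.film_y[:] = 0.0
        open_ = LeadFieldSolver(cmap2).solve_as((0, 4))
        # probe inside a fascicle away from the driven site
        c = toy_nerve.fascicles[0].centroid
        p = np.array([[c[0], c[1], 0.0]])
        assert abs(shielded.at(p, 1e-6)[0]) < abs(open_.at(p, 1e-6)[0])

    def test_discrete_conservation_residual(self, toy_time_setup):
        solver = LeadFieldSolver(toy_time_setup["cmap"])
        sysm = solver.system
        rhs = np.zeros(sysm.n)
        (i, j, k, frac) = toy_time_setup["cmap"].sources[(0, 0)][0]
        rhs[sysm.idx[i, j, k]] = frac
        x = sysm.solve(rhs)
        # per-cell current balance (KCL) holds to solver tolerance, hence the
        # net current through any closed source-free surface vanishes
        res = np.abs(sysm.A @ x - rhs)
        assert res.max() <= 1e-6 * np.abs(rhs).max()
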