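"""Wall FEM: constitutive law, static inflation, pre-stress estimation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from aaafsi import geometry as geo
from aaafsi import wall_fem as wf

from conftest import make_tube_stack


class TestNeoHookean:
    def test_identity_deformation_gives_pure_pressure(self):
        sigma = wf.neo_hookean_cauchy(np.eye(3), G=1.0, p=2.5)
        assert np.allclose(sigma, -2.5 * np.eye(3))

    def test_simple_shear_stress(self):
        gamma = 0.3
        F = np.eye(3)
        F[0, 1] = gamma
        sigma = wf.neo_hookean_cauchy(F, G=0.92, p=0.0)
        assert sigma[0, 1] == pytest.approx(0.92 * gamma)
        assert sigma[1, 0] == pytest.approx(0.92 * gamma)

    def test_incompressible_uniaxial_stretch(self):
        lam, G = 1.4, 1.02
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        # eliminate p from the traction-free lateral faces: p = G(1/lam - 1)
        p = G * (1.0 / lam - 1.0)
        sigma = wf.neo_hookean_cauchy(F, G=G, p=p)
        assert sigma[0, 0] == pytest.approx(G * (lam**2 - 1.0 / lam))
        assert sigma[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_penalty_pressure_vanishes_at_unit_volume(self):
        assert wf.penalty_pressure(np.eye(3), G=1.0) == 0.0

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            wf.neo_hookean_cauchy(np.diag([-1.0, 1.0, 1.0]), G=1.0, p=0.0)

    def test_rigid_rotation_is_stress_free(self):
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        sigma = wf.neo_hookean_cauchy(R, G=1.36)
        assert np.allclose(sigma, 0.0, atol=1e-12)


class TestGroupModuli:
    @pytest.mark.parametrize("group,G", [("S", 0.92), ("M", 1.02), ("L", 1.36)])
    def test_group_shear_moduli(self, group, G):
        mat = wf.assign_shear_modulus(group)
        assert mat.G == G
        assert mat.E == pytest.approx(2.0 * G * (1.0 + mat.nu))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            wf.assign_shear_modulus("XL")


class TestVonMises:
    def test_hydrostatic_state_has_zero_equivalent_stress(self):
        assert wf.von_mises(-3.7 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_equals_axial_stress(self):
        s = np.zeros((3, 3))
        s[0, 0] = 42.0
        assert wf.von_mises(s) == pytest.approx(42.0)

    def test_pure_shear(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 5.0
        assert wf.von_mises(s) == pytest.approx(np.sqrt(3.0) * 5.0)


class TestStaticInflation:
    def test_zero_pressure_keeps_rest_state(self, thick_tube_mesh):
        mat = wf.Material(G=0.92)
        state = wf.solve_static_inflation(thick_tube_mesh, mat, 0.0)
        assert np.abs(state.displacement).max() == pytest.approx(0.0, abs=1e-12)
        assert np.abs(state.cauchy_stress).max() == pytest.approx(0.0, abs=1e-9)

    def test_thick_tube_matches_incompressible_cylinder(self, thick_tube_mesh):
        """1D incompressible plane-strain inflation relation as oracle."""
        G, P = 0.92e6, 70 * 133.322
        A, B = 0.010, 0.012

        def applied_pressure(a):
            b = np.sqrt(B**2 - A**2 + a**2)
            integrand = lambda r: (
                G * (r**2 / (r**2 - a**2 + A**2) - (r**2 - a**2 + A**2) / r**2) / r
            )
            return quad(integrand, a, b)[0]

        a_exact = brentq(lambda a: applied_pressure(a) - P, A, 1.2 * A)
        u_exact = (a_exact - A) * 1e3  # mm

        mat = wf.Material(G=0.92)
        state = wf.solve_static_inflation(thick_tube_mesh, mat, 70.0)
        lum = thick_tube_mesh.node_sets["luminal"]
        x = thick_tube_mesh.nodes + state.displacement
        u_fem = np.linalg.norm(x[lum][:, :2], axis=1).mean() - 10.0
        assert abs(u_fem - u_exact) / u_exact < 0.02

    def test_negative_pressure_rejected(self, thick_tube_mesh):
        with pytest.raises(ValueError):
            wf.solve_static_inflation(thick_tube_mesh, wf.Material(G=1.0), -5.0)

    def test_end_constraints_are_radial_only(self, thick_tube_mesh):
        mat = wf.Material(G=0.92)
        state = wf.solve_static_inflation(thick_tube_mesh, mat, 70.0)
        ends = np.concatenate(
            [thick_tube_mesh.node_sets["inlet_ring"], thick_tube_mesh.node_sets["outlet_ring"]]
        )
        # no axial motion on the constrained cross-sections
        assert np.abs(state.displacement[ends, 2]).max() < 1e-10


class TestBimPrestress:
    def test_pressure_schedule_endpoints(self):
        sched = wf.bim_pressure_schedule(80.0, i_max=20)
        assert sched[-1] == pytest.approx(80.0)
        assert sched[9] == pytest.approx(80.0 * np.sin(np.pi / 4.0))
        assert len(sched) == 20

    def test_thin_tube_hoop_stress_matches_laplace(self):
        """After pre-stress at p_m the mean hoop Cauchy stress is p r / h."""
        stack = make_tube_stack(radius=40.0, length=40.0, n=5)
        mesh = geo.extrude_wall_mesh(geo.build_lumen_surface(stack, target_edge=8.0))
        mat = wf.Material(G=1.36)
        pre = wf.bim_prestress(mesh, mat, 70.0)
        assert pre.prestressed
        assert np.abs(pre.displacement).max() == 0.0

        from aaafsi.elements import HEX_N

        xg = np.einsum("gn,eni->egi", HEX_N, mesh.nodes[mesh.hex_elements])
        e_th = np.stack([-xg[..., 1], xg[..., 0], np.zeros_like(xg[..., 0])], axis=-1)
        e_th /= np.linalg.norm(e_th, axis=-1, keepdims=True)
        hoop = np.einsum("egi,egij,egj->eg", e_th, pre.cauchy_stress * 1e3, e_th)
        laplace = 70 * 133.322 * 41.0 / 2.0  # mid-wall radius over thickness
        assert abs(hoop.mean() - laplace) / laplace < 0.05

    def test_invalid_pressure_rejected(self, thick_tube_mesh):
        with pytest.raises(ValueError):
            wf.bim_prestress(thick_tube_mesh, wf.Material(G=1.0), 0.0)


class TestEnergyConsistency:
    def test_pressure_work_matches_strain_energy(self, thick_tube_mesh):
        """Quasi-static follower-load work equals stored hyperelastic energy."""
        mesh = thick_tube_mesh
        mat = wf.Material(G=0.92)
        fem = wf.WallFem(mesh, mat)
        lum = mesh.node_sets["luminal"]
        surf = mesh.surface

        n_steps = 20
        pressures = np.linspace(0.0, 70.0, n_steps + 1)
        vols = [geo.enclosed_lumen_volume(surf)]
        u = None
        for p in pressures[1:]:
            u, sig, _ = fem.solve(fem.nodal_pressure(p), u0=u, reuse_factor=True)
            vols.append(
                geo.enclosed_lumen_volume(surf.with_nodes(mesh.nodes[lum] + u[lum] * 1e3))
            )
        work = 0.0
        for k in range(n_steps):
            p_mid = 0.5 * (pressures[k] + pressures[k + 1]) * 133.322  # Pa
            work += p_mid * (vols[k + 1] - vols[k]) * 1e-9  # J
        energy = fem.strain_energy(u)
        assert abs(work - energy) / energy < 0.01


class TestStressDiameterTrend:
    def test_p99_stress_increases_with_max_diameter(self):
        """Larger aneurysms carry higher peak systolic wall stress."""
        p99 = []
        for d, group in ((33.0, "S"), (47.0, "M"), (53.0, "L")):
            prof = geo.AaaProfile(max_diameter=d, n_contours=25, noise_sd=0.0)
            stack = geo.generate_synthetic_aaa(prof, seed=11)
            mesh = geo.extrude_wall_mesh(
                geo.build_lumen_surface(geo.elongate_contours(stack), target_edge=7.5)
            )
            mat = wf.assign_shear_modulus(group)
            fem = wf.WallFem(mesh, mat)
            pre = wf.bim_prestress(mesh, mat, 71.28, fem=fem)
            sys_state = wf.solve_static_inflation(mesh, mat, 141.75, initial=pre, fem=fem)
            vm = wf.von_mises(sys_state.cauchy_stress)
            p99.append(np.percentile(vm, 99))
        assert p99[0] < p99[1] < p99[2]
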