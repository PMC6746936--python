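"""Impact model and plane-stress solver: closed forms, patch test, beam."""

import math

import numpy as np
import pytest

from dxafem.impact import ImpactParameters, impact_force, impact_force_numeric
from dxafem.meshing import build_mesh
from dxafem.solver import principal_strains, solve_plane_stress


class TestImpactForce:
    def test_undamped_closed_form(self):
        p = ImpactParameters(body_height_m=1.6, body_mass_kg=70.0)
        v = math.sqrt(2 * 9.81 * 0.51 * 1.6)
        assert p.impact_velocity == pytest.approx(v, rel=1e-12)
        assert impact_force(p) == pytest.approx(v * math.sqrt(5.0e4 * 35.0), rel=1e-12)

    def test_quadrupled_stiffness_doubles_force(self):
        p1 = ImpactParameters(1.6, 70.0)
        p4 = ImpactParameters(1.6, 70.0, contact_stiffness_k=4 * 5.0e4)
        assert impact_force(p4) == pytest.approx(2 * impact_force(p1), rel=1e-12)

    @pytest.mark.parametrize("zeta", [0.05, 0.2, 0.5])
    def test_damped_closed_form_matches_time_integration(self, zeta):
        p = ImpactParameters(1.65, 62.0, damping_ratio_zeta=zeta)
        assert impact_force_numeric(p) == pytest.approx(impact_force(p), rel=1e-4)

    def test_damped_converges_to_undamped_limit(self):
        p0 = ImpactParameters(1.6, 70.0)
        p_small = ImpactParameters(1.6, 70.0, damping_ratio_zeta=5e-4)
        assert impact_force_numeric(p_small) == pytest.approx(
            impact_force(p0), rel=1e-3
        )

    def test_overdamped_rejected(self):
        with pytest.raises(ValueError):
            ImpactParameters(1.6, 70.0, damping_ratio_zeta=1.0)


def _square_plate(n=20, h=0.5, e=1000.0, nu=0.3, t=2.0):
    mesh = build_mesh(np.ones((n, n), bool), h, h, thickness_t=t)
    return mesh, np.full(mesh.n_elements, e), nu, t


def _edge_traction(mesh, sigma, t, h, side_x):
    nodes = mesh.nodes
    edge = np.nonzero(np.isclose(nodes[:, 0], side_x))[0]
    ymin, ymax = nodes[edge, 1].min(), nodes[edge, 1].max()
    f = np.zeros(2 * mesh.n_nodes)
    for nd in edge:
        frac = 0.5 if np.isclose(nodes[nd, 1], ymin) or np.isclose(nodes[nd, 1], ymax) else 1.0
        f[2 * nd] = sigma * t * h * frac
    return f, edge


class TestSolver:
    def test_patch_uniform_traction_exact(self):
        """Uniform traction on a homogeneous square: exact uniform strain."""
        mesh, e, nu, t = _square_plate()
        sigma = 5.0
        f, _ = _edge_traction(mesh, sigma, t, 0.5, 10.0)
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        fixed = list(2 * left) + [2 * left[np.argmin(mesh.nodes[left, 1])] + 1]
        res = solve_plane_stress(
            mesh.nodes, mesh.elements, e, nu, t, f, fixed_dofs=np.array(fixed)
        )
        exx_exact = sigma / 1000.0
        assert np.abs(res.strains[:, 0] - exx_exact).max() / exx_exact < 1e-10
        assert np.abs(res.strains[:, 1] + nu * exx_exact).max() / exx_exact < 1e-10
        assert np.abs(res.strains[:, 2]).max() / exx_exact < 1e-10
        assert res.equilibrium_residual < 1e-10

    def test_cantilever_tip_deflection_beam_oracle(self):
        """100 x 10 mm strip, tip shear load, 0.5 mm mesh, vs the
        shear-corrected closed-form beam deflection PL^3/3EI + PL/(k G A)."""
        length, depth, h, e_mod, nu, t, p_load = 100.0, 10.0, 0.5, 10000.0, 0.3, 3.0, 100.0
        mesh = build_mesh(
            np.ones((int(depth / h), int(length / h)), bool), h, h, thickness_t=t
        )
        e = np.full(mesh.n_elements, e_mod)
        nodes = mesh.nodes
        left = np.nonzero(np.isclose(nodes[:, 0], 0.0))[0]
        right = np.nonzero(np.isclose(nodes[:, 0], length))[0]
        f = np.zeros(2 * mesh.n_nodes)
        for nd in right:
            frac = 0.5 if np.isclose(nodes[nd, 1], 0) or np.isclose(nodes[nd, 1], depth) else 1.0
            f[2 * nd + 1] = -p_load * frac / (len(right) - 1)
        fixed = np.concatenate([2 * left, 2 * left + 1])
        res = solve_plane_stress(nodes, mesh.elements, e, nu, t, f, fixed_dofs=fixed)
        tip = right[np.argmin(np.abs(nodes[right, 1] - depth / 2))]
        inertia = t * depth**3 / 12
        shear_mod = e_mod / (2 * (1 + nu))
        ref = -(
            p_load * length**3 / (3 * e_mod * inertia)
            + p_load * length / (5 / 6 * shear_mod * t * depth)
        )
        assert res.u[2 * tip + 1] == pytest.approx(ref, rel=0.02)

    def test_doubling_moduli_halves_displacements(self):
        mesh, e, nu, t = _square_plate(n=10)
        f, _ = _edge_traction(mesh, 3.0, t, 0.5, 5.0)
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        fixed = np.concatenate([2 * left, 2 * left + 1])
        r1 = solve_plane_stress(mesh.nodes, mesh.elements, e, nu, t, f, fixed_dofs=fixed)
        r2 = solve_plane_stress(mesh.nodes, mesh.elements, 2 * e, nu, t, f, fixed_dofs=fixed)
        np.testing.assert_allclose(r2.u, r1.u / 2, atol=1e-12)

    def test_rotation_invariance_of_solution(self):
        """Rotating mesh, load and constraints rotates the displacements."""
        mesh, e, nu, t = _square_plate(n=8)
        f, _ = _edge_traction(mesh, 4.0, t, 0.5, 4.0)
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        fixed = np.concatenate([2 * left, 2 * left + 1])
        r1 = solve_plane_stress(mesh.nodes, mesh.elements, e, nu, t, f, fixed_dofs=fixed)

        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        nodes_rot = mesh.nodes @ rot.T
        f_rot = (f.reshape(-1, 2) @ rot.T).ravel()
        # rotated fixed dofs: constrain both components of the same nodes
        fixed_rot = np.concatenate([2 * left, 2 * left + 1])
        r2 = solve_plane_stress(
            nodes_rot, mesh.elements, e, nu, t, f_rot, fixed_dofs=fixed_rot
        )
        u1_rot = (r1.u.reshape(-1, 2) @ rot.T).ravel()
        np.testing.assert_allclose(r2.u, u1_rot, atol=1e-10)

    def test_insufficient_constraints_detected(self):
        mesh, e, nu, t = _square_plate(n=4)
        f = np.zeros(2 * mesh.n_nodes)
        f[0] = 1.0
        with pytest.raises(ValueError, match="singular|insufficient"):
            solve_plane_stress(mesh.nodes, mesh.elements, e, nu, t, f)

    def test_nonpositive_modulus_named(self):
        mesh, e, nu, t = _square_plate(n=4)
        e[3] = -1.0
        with pytest.raises(ValueError, match=r"\[3\]"):
            solve_plane_stress(
                mesh.nodes, mesh.elements, e, nu, t, np.zeros(2 * mesh.n_nodes),
                fixed_dofs=np.arange(4),
            )


class TestPrincipalStrains:
    def test_diagonal_tensor(self):
        e1, e3 = principal_strains(np.array([0.001, -0.001, 0.0]))
        assert e1 == pytest.approx(0.001)
        assert e3 == pytest.approx(-0.001)

    def test_pure_shear(self):
        e1, e3 = principal_strains(np.array([0.0, 0.0, 0.002]))
        assert e1 == pytest.approx(0.001)
        assert e3 == pytest.approx(-0.001)

    def test_hydrostatic(self):
        for a in (-0.004, 0.0, 0.003):
            e1, e3 = principal_strains(np.array([a, a, 0.0]))
            assert e1 == pytest.approx(a)
            assert e3 == pytest.approx(a)

    def test_against_eigendecomposition_on_random_tensors(self, rng):
        s = rng.normal(scale=0.01, size=(1000, 3))
        e1, e3 = principal_strains(s)
        for i in range(1000):
            tensor = np.array(
                [[s[i, 0], s[i, 2] / 2], [s[i, 2] / 2, s[i, 1]]]
            )
            lo, hi = np.linalg.eigvalsh(tensor)
            assert abs(e1[i] - hi) < 1e-12
            assert abs(e3[i] - lo) < 1e-12
        assert np.all(e1 >= e3)
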