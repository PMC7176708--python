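"""Solver correctness: element oracle, patch test, closed-form benchmarks."""

import numpy as np
import pytest

from mandifem.errors import SolverError
from mandifem.fem import (
    Material,
    element_stiffness,
    gauss_rule,
    solve,
    von_mises_plane_stress,
)
from mandifem.meshing import structured_rect_mesh

UNIT_SQUARE_Q8 = np.array(
    [
        [0, 0], [1, 0], [1, 1], [0, 1],
        [0.5, 0], [1, 0.5], [0.5, 1], [0, 0.5],
    ],
    dtype=float,
)


def oracle_stiffness(coords, e, nu, t, n_gauss=6):
    """Brute-force QUAD8 stiffness, independent of the solver internals.

    Shape functions are obtained numerically by inverting the Vandermonde
    matrix of the serendipity monomial basis at the parent nodes, their
    gradients by central finite differences, and the integral by a dense
    Gauss grid.
    """
    parent = np.array(
        [
            [-1, -1], [1, -1], [1, 1], [-1, 1],
            [0, -1], [1, 0], [0, 1], [-1, 0],
        ],
        dtype=float,
    )

    def monomials(xi, eta):
        return np.array(
            [1.0, xi, eta, xi * xi, xi * eta, eta * eta, xi * xi * eta, xi * eta * eta]
        )

    v = np.array([monomials(x, y) for x, y in parent])
    inv_v = np.linalg.inv(v)

    def shapes(xi, eta):
        return inv_v.T @ monomials(xi, eta)

    def dshapes(xi, eta, h=1e-6):
        dxi = (shapes(xi + h, eta) - shapes(xi - h, eta)) / (2 * h)
        deta = (shapes(xi, eta + h) - shapes(xi, eta - h)) / (2 * h)
        return np.column_stack([dxi, deta])

    d = (e / (1 - nu**2)) * np.array(
        [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]]
    )
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    k = np.zeros((16, 16))
    for xi, wx in zip(pts, wts):
        for eta, wy in zip(pts, wts):
            dn = dshapes(xi, eta)
            jac = dn.T @ coords
            det = np.linalg.det(jac)
            grad = np.linalg.inv(jac) @ dn.T
            b = np.zeros((3, 16))
            b[0, 0::2] = grad[0]
            b[1, 1::2] = grad[1]
            b[2, 0::2] = grad[1]
            b[2, 1::2] = grad[0]
            k += b.T @ d @ b * det * t * wx * wy
    return k


class TestElementStiffness:
    def test_matches_quadrature_oracle_unit_square(self):
        k = element_stiffness(UNIT_SQUARE_Q8, Material(1.0, 0.0), 1.0, order=3)
        k_oracle = oracle_stiffness(UNIT_SQUARE_Q8, 1.0, 0.0, 1.0)
        np.testing.assert_allclose(k, k_oracle, atol=1e-8)

    def test_matches_oracle_parallelogram(self):
        # affine map keeps the integrand polynomial, so 3x3 Gauss is exact
        a = np.array([[1.0, 0.3], [0.1, 0.9]])
        coords = UNIT_SQUARE_Q8 @ a.T
        k = element_stiffness(coords, Material(210.0, 0.3), 2.5, order=3)
        k_oracle = oracle_stiffness(coords, 210.0, 0.3, 2.5)
        np.testing.assert_allclose(k, k_oracle, atol=1e-6 * np.abs(k_oracle).max())

    def test_symmetric(self):
        k = element_stiffness(UNIT_SQUARE_Q8, Material(21000.0, 0.45), 5.0)
        assert np.abs(k - k.T).max() <= 1e-12 * np.abs(k).max()

    def test_rigid_body_modes(self):
        k = element_stiffness(UNIT_SQUARE_Q8, Material(1.0, 0.2), 1.0, order=3)
        # translations and an infinitesimal rotation produce zero force
        tx = np.tile([1.0, 0.0], 8)
        ty = np.tile([0.0, 1.0], 8)
        rot = np.column_stack([-UNIT_SQUARE_Q8[:, 1], UNIT_SQUARE_Q8[:, 0]]).ravel()
        for u in (tx, ty, rot):
            assert np.abs(k @ u).max() < 1e-12
        # full integration leaves exactly 3 zero-energy modes
        w = np.linalg.eigvalsh(k)
        assert np.sum(np.abs(w) < 1e-10 * np.abs(w).max()) == 3


class TestVonMises:
    @pytest.mark.parametrize(
        "sx,sy,txy,expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (7.0, 7.0, 0.0, 7.0),
            (0.0, 0.0, 1.0, np.sqrt(3.0)),
        ],
    )
    def test_reference_values(self, sx, sy, txy, expected):
        assert von_mises_plane_stress(sx, sy, txy) == pytest.approx(expected, rel=1e-12)

    def test_non_negative_on_random_states(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(1000, 3)) * 100
        assert np.all(von_mises_plane_stress(s[:, 0], s[:, 1], s[:, 2]) >= 0)


def _distorted_patch():
    """2x2 patch with an off-grid interior corner node (midsides recomputed)."""
    mesh = structured_rect_mesh(2.0, 2.0, 2, 2)
    nodes = mesh.nodes.copy()
    interior_corner = np.where(
        (np.abs(nodes[:, 0] - 1.0) < 1e-12) & (np.abs(nodes[:, 1] - 1.0) < 1e-12)
    )[0][0]
    nodes[interior_corner] = [1.13, 0.87]
    for el in mesh.elements:
        for j in range(4):
            a, b = el[j], el[(j + 1) % 4]
            nodes[el[4 + j]] = 0.5 * (nodes[a] + nodes[b])
    mesh.nodes = nodes
    return mesh


class TestSolve:
    def test_constant_strain_patch(self):
        """A linear displacement field imposed on the boundary is reproduced
        exactly on a distorted patch (constant stress everywhere)."""
        mesh = _distorted_patch()
        mat = Material(21000.0, 0.45)

        def field(p):
            return np.array([1e-3 * p[0] + 2e-4 * p[1], -3e-4 * p[0] + 5e-4 * p[1]])

        fixed = {}
        for n in mesh.boundary_node_indices():
            u = field(mesh.nodes[n])
            fixed[(int(n), 0)] = u[0]
            fixed[(int(n), 1)] = u[1]
        sf = solve(mesh, mat, 3.0, np.zeros_like(mesh.nodes), fixed)
        # exact stresses from the constant strain state
        ex, ey, gxy = 1e-3, 5e-4, 2e-4 - 3e-4
        d = mat.d_matrix()
        s_exact = d @ np.array([ex, ey, gxy])
        for comp in range(3):
            np.testing.assert_allclose(
                sf.element_components[:, comp], s_exact[comp], rtol=1e-9
            )
        for n in range(mesh.n_nodes):
            np.testing.assert_allclose(
                sf.nodal_displacements[n], field(mesh.nodes[n]), atol=1e-12
            )

    def test_zero_load_gives_zero_field(self, mandible_mesh):
        mesh = mandible_mesh
        fixed = {(0, 0): 0.0, (0, 1): 0.0, (5, 1): 0.0}
        sf = solve(mesh, Material(21000.0, 0.45), 10.0, np.zeros((mesh.n_nodes, 2)), fixed)
        assert np.all(sf.element_vm == 0.0)
        assert np.all(sf.nodal_displacements == 0.0)

    def test_under_constrained_raises(self):
        mesh = structured_rect_mesh(1.0, 1.0, 2, 2)
        with pytest.raises(SolverError, match="rigid-body"):
            solve(
                mesh,
                Material(1.0, 0.0),
                1.0,
                np.zeros((mesh.n_nodes, 2)),
                {(0, 0): 0.0, (1, 0): 0.0, (2, 0): 0.0},  # nothing holds y
            )


def _end_loaded_strip(nx=8, ny=2, length=40.0, width=10.0, force=100.0, axis=0):
    """Structured strip with a consistent uniform end traction."""
    mesh = structured_rect_mesh(length, width, nx, ny)
    nodes = mesh.nodes
    forces = np.zeros((mesh.n_nodes, 2))
    right = np.where(np.abs(nodes[:, 0] - length) < 1e-9)[0]
    eln = width / ny
    q = force / width
    for n in right:
        y = nodes[n, 1]
        k = y / eln
        if abs(k - round(k)) < 1e-9:  # corner node
            share = 1 / 6 if round(k) in (0, ny) else 2 / 6
        else:  # mid-side node
            share = 2 / 3
        forces[n, axis] = q * eln * share
    return mesh, forces, right


class TestBenchmarks:
    def test_uniaxial_strip_uniform_stress(self):
        """Axial end load F on a w x t strip gives sigma_vm = F/(w t) everywhere."""
        length, width, t, force = 40.0, 10.0, 5.0, 100.0
        mesh, forces, _ = _end_loaded_strip(length=length, width=width, force=force)
        left = np.where(np.abs(mesh.nodes[:, 0]) < 1e-9)[0]
        fixed = {(int(n), 0): 0.0 for n in left}
        corner = int(left[np.argmin(mesh.nodes[left, 1])])
        fixed[(corner, 1)] = 0.0
        sf = solve(mesh, Material(21000.0, 0.45), t, forces, fixed)
        np.testing.assert_allclose(sf.element_vm, force / (width * t), rtol=1e-6)
        # reactions balance the applied load
        total = sf.reactions.sum(axis=0) + forces.sum(axis=0)
        assert np.abs(total).max() < 1e-8 * force

    def test_cantilever_tip_deflection(self):
        """Tip deflection approaches P L^3 / (3 E I) (Euler-Bernoulli)."""
        length, h, t, p, e = 100.0, 10.0, 5.0, 10.0, 21000.0
        mesh, forces, right = _end_loaded_strip(
            nx=60, ny=6, length=length, width=h, force=-p, axis=1
        )
        left = np.where(np.abs(mesh.nodes[:, 0]) < 1e-9)[0]
        fixed = {}
        for n in left:
            fixed[(int(n), 0)] = 0.0
            fixed[(int(n), 1)] = 0.0
        sf = solve(mesh, Material(e, 0.3), t, forces, fixed)
        tip = right[np.argmin(np.abs(mesh.nodes[right, 1] - h / 2))]
        inertia = t * h**3 / 12.0
        expected = -p * length**3 / (3 * e * inertia)
        assert sf.nodal_displacements[tip, 1] == pytest.approx(expected, rel=0.03)

    def test_refinement_is_monotone(self):
        """Tip deflection converges monotonically under mesh refinement.

        The converged value exceeds Euler-Bernoulli slightly (shear
        deformation), so monotonicity is checked against a fine-mesh
        reference solution.
        """
        length, h, t, p, e = 100.0, 10.0, 5.0, 10.0, 21000.0

        def tip_deflection(nx, ny):
            mesh, forces, right = _end_loaded_strip(
                nx=nx, ny=ny, length=length, width=h, force=-p, axis=1
            )
            left = np.where(np.abs(mesh.nodes[:, 0]) < 1e-9)[0]
            fixed = {(int(n), d): 0.0 for n in left for d in (0, 1)}
            sf = solve(mesh, Material(e, 0.3), t, forces, fixed)
            tip = right[np.argmin(np.abs(mesh.nodes[right, 1] - h / 2))]
            return sf.nodal_displacements[tip, 1]

        reference = tip_deflection(160, 16)
        errs = [abs(tip_deflection(nx, ny) - reference) for nx, ny in ((20, 2), (40, 4), (80, 8))]
        assert errs[0] > errs[1] > errs[2]

    def test_rotation_invariance(self):
        """Rotating model and loads together leaves von Mises unchanged."""
        length, h, t, p = 60.0, 10.0, 5.0, 10.0
        mesh, forces, _ = _end_loaded_strip(
            nx=24, ny=4, length=length, width=h, force=-p, axis=1
        )
        left = np.where(np.abs(mesh.nodes[:, 0]) < 1e-9)[0]
        fixed = {(int(n), d): 0.0 for n in left for d in (0, 1)}
        mat = Material(21000.0, 0.45)
        sf0 = solve(mesh, mat, t, forces, fixed)

        th = np.deg2rad(37.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mesh.nodes = mesh.nodes @ rot.T
        sf1 = solve(mesh, mat, t, forces @ rot.T, fixed)
        np.testing.assert_allclose(sf1.element_vm, sf0.element_vm, rtol=1e-8)
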