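"""Linear-elastic 2D plane-stress finite-element solver on QUAD8 meshes.

The mandible models are thin, plate-like structures loaded in their own
plane, so the through-thickness stresses are neglected (plane stress).
Elements are 8-node serendipity quadrilaterals with straight sides;
stiffness and stress recovery use 2x2 Gauss quadrature by default (the
standard reduced scheme for this element), with full 3x3 integration
available for rank checks.

Units are fixed as mm / N / MPa throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError, InvalidArgumentError, SolverError

__all__ = [
    "Material",
    "StressField",
    "element_stiffness",
    "solve",
    "solve_case",
    "von_mises_plane_stress",
]

# Parent-domain node coordinates: 4 corners CCW, then 4 mid-side nodes
# (between corners 0-1, 1-2, 2-3, 3-0).
_XI = np.array([-1.0, 1.0, 1.0, -1.0, 0.0, 1.0, 0.0, -1.0])
_ETA = np.array([-1.0, -1.0, 1.0, 1.0, -1.0, 0.0, 1.0, 0.0])


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (plane stress).

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus in MPa (cortical bone default elsewhere: 21000 MPa).
    poisson_ratio : float
        Poisson ratio, ``0 <= nu < 0.5``.
    """

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise InvalidArgumentError("youngs_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise InvalidArgumentError("poisson_ratio must be in [0, 0.5)")

    def d_matrix(self) -> np.ndarray:
        """3x3 plane-stress constitutive matrix (MPa)."""
        e, nu = self.youngs_modulus, self.poisson_ratio
        return (e / (1.0 - nu**2)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
        )


# Default material from a Macaca mandible: E = 21 GPa, nu = 0.45.
BONE = Material(youngs_modulus=21000.0, poisson_ratio=0.45)


@dataclass
class StressField:
    """Solution of one load case.

    ``element_vm`` and ``element_components`` hold one value (set) per
    element: the von Mises stress is evaluated at each Gauss point and
    averaged over the element weighted by the Gauss-point tributary area,
    because the downstream percentile statistic needs a single value per
    element.
    """

    element_vm: np.ndarray  # (ne,) MPa
    element_components: np.ndarray  # (ne, 3) = (sx, sy, txy) MPa
    nodal_displacements: np.ndarray  # (nn, 2) mm
    reactions: np.ndarray = field(default=None, repr=False)  # (nn, 2) N


def shape_functions(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Serendipity QUAD8 shape functions and parent-domain gradients.

    Returns ``(N, dN)`` with ``N`` of shape (8,) and ``dN`` of shape (8, 2)
    holding (dN/dxi, dN/deta).
    """
    n = np.empty(8)
    dn = np.empty((8, 2))
    for i in range(4):
        xi_i, eta_i = _XI[i], _ETA[i]
        n[i] = 0.25 * (1 + xi * xi_i) * (1 + eta * eta_i) * (xi * xi_i + eta * eta_i - 1)
        dn[i, 0] = 0.25 * xi_i * (1 + eta * eta_i) * (2 * xi * xi_i + eta * eta_i)
        dn[i, 1] = 0.25 * eta_i * (1 + xi * xi_i) * (xi * xi_i + 2 * eta * eta_i)
    for i in range(4, 8):
        xi_i, eta_i = _XI[i], _ETA[i]
        if xi_i == 0.0:  # mid-side node on an eta = +-1 edge
            n[i] = 0.5 * (1 - xi**2) * (1 + eta * eta_i)
            dn[i, 0] = -xi * (1 + eta * eta_i)
            dn[i, 1] = 0.5 * (1 - xi**2) * eta_i
        else:  # mid-side node on a xi = +-1 edge
            n[i] = 0.5 * (1 + xi * xi_i) * (1 - eta**2)
            dn[i, 0] = 0.5 * xi_i * (1 - eta**2)
            dn[i, 1] = -eta * (1 + xi * xi_i)
    return n, dn


def gauss_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss points and weights on [-1, 1]^2."""
    pts1, wts1 = np.polynomial.legendre.leggauss(order)
    pts = np.array([(xi, eta) for eta in pts1 for xi in pts1])
    wts = np.array([wx * wy for wy in wts1 for wx in wts1])
    return pts, wts


def _precompute_dn(order: int) -> tuple[np.ndarray, np.ndarray]:
    pts, wts = gauss_rule(order)
    dn = np.stack([shape_functions(xi, eta)[1] for xi, eta in pts])  # (g, 8, 2)
    return dn, wts


def element_stiffness(
    coords: np.ndarray,
    material: Material,
    thickness: float,
    order: int = 2,
) -> np.ndarray:
    """Stiffness matrix (16x16, N/mm) of a single straight-sided QUAD8.

    ``coords`` is the 8x2 node coordinate array (corners CCW then
    mid-sides).  Raises :class:`GeometryError` on a degenerate element
    (non-positive Jacobian at any quadrature point).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (8, 2):
        raise InvalidArgumentError("coords must have shape (8, 2)")
    if thickness <= 0:
        raise InvalidArgumentError("thickness must be > 0")
    k = _stiffness_batch(coords[None], material.d_matrix(), thickness, order)[0]
    return k


def _jacobians(coords: np.ndarray, dn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jacobians for a batch of elements at all Gauss points.

    coords: (ne, 8, 2); dn: (g, 8, 2).  Returns (J (ne, g, 2, 2), detJ (ne, g)).
    """
    # J[e, g, a, b] = sum_i dN[g, i, a] * coords[e, i, b]
    jac = np.einsum("gia,eib->egab", dn, coords)
    det = jac[..., 0, 0] * jac[..., 1, 1] - jac[..., 0, 1] * jac[..., 1, 0]
    return jac, det


def _stiffness_batch(
    coords: np.ndarray, d: np.ndarray, thickness, order: int
) -> np.ndarray:
    """Vectorised QUAD8 stiffness for a batch of elements (ne, 16, 16)."""
    dn, wts = _precompute_dn(order)
    jac, det = _jacobians(coords, dn)
    if np.any(det <= 0):
        bad = int(np.argwhere(det <= 0)[0][0])
        raise GeometryError(f"non-positive Jacobian in element {bad}")
    inv = np.linalg.inv(jac)  # (ne, g, 2, 2)
    # Cartesian gradients: grad[e, g, i, a] = inv[e, g, a, b] * dn[g, i, b]
    grad = np.einsum("egab,gib->egia", inv, dn)
    ne, g = det.shape
    b = np.zeros((ne, g, 3, 16))
    b[:, :, 0, 0::2] = grad[..., 0]
    b[:, :, 1, 1::2] = grad[..., 1]
    b[:, :, 2, 0::2] = grad[..., 1]
    b[:, :, 2, 1::2] = grad[..., 0]
    t = np.broadcast_to(np.asarray(thickness, dtype=float), (ne,))
    scale = det * wts[None, :] * t[:, None]  # (ne, g)
    return np.einsum("egki,kl,eglj,eg->eij", b, d, b, scale, optimize=True)


def von_mises_plane_stress(sx, sy, txy):
    """Von Mises equivalent stress in plane stress (element-wise).

    sigma_vm = sqrt(sx^2 + sy^2 - sx*sy + 3*txy^2); the standard yield
    criterion for ductile isotropic materials such as cortical bone under
    the isotropy assumption.
    """
    sx = np.asarray(sx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    txy = np.asarray(txy, dtype=float)
    return np.sqrt(np.maximum(sx**2 + sy**2 - sx * sy + 3.0 * txy**2, 0.0))


def _rigid_mode_name(fixed_dofs: np.ndarray, nodes: np.ndarray) -> str:
    dofs = set(int(d) % 2 for d in fixed_dofs)
    if 0 not in dofs:
        return "translation-x"
    if 1 not in dofs:
        return "translation-y"
    constrained_nodes = {int(d) // 2 for d in fixed_dofs}
    if len(constrained_nodes) == 1:
        return "rotation about the single constrained node"
    return "in-plane rotation"


def solve(
    mesh,
    material: Material,
    thickness: float,
    forces: np.ndarray,
    fixed: dict,
    order: int = 2,
) -> StressField:
    """Solve one static load case.

    Parameters
    ----------
    mesh : QuadMesh
        Mesh with ``nodes`` (nn, 2) and ``elements`` (ne, 8).
    forces : (nn, 2) array
        Applied nodal forces in N.
    fixed : dict
        ``{(node_index, dof): prescribed_displacement_mm}``; dof 0 = x,
        dof 1 = y.  Prescribed values may be non-zero (used e.g. by the
        constant-strain patch test).

    Returns
    -------
    StressField
        Element stresses, nodal displacements, and reactions at the
        constrained dofs (zero elsewhere).  Global equilibrium (reactions
        balancing applied loads) holds to solver precision.
    """
    nodes = np.asarray(mesh.nodes, dtype=float)
    elements = np.asarray(mesh.elements, dtype=np.int64)
    nn = nodes.shape[0]
    ne = elements.shape[0]
    ndof = 2 * nn

    forces = np.asarray(forces, dtype=float)
    if forces.shape != (nn, 2):
        raise InvalidArgumentError(f"forces must have shape ({nn}, 2)")

    fixed_dofs = np.array(sorted(n * 2 + d for (n, d) in fixed), dtype=np.int64)
    fixed_vals = np.array([fixed[(d // 2, d % 2)] for d in fixed_dofs], dtype=float)
    directions = {int(d) % 2 for d in fixed_dofs}
    constrained_nodes = {int(d) // 2 for d in fixed_dofs}
    under = (
        len(fixed_dofs) < 3
        or directions != {0, 1}
        or len(constrained_nodes) < 2
    )
    if under:
        raise SolverError(
            "under-constrained model: free rigid-body mode "
            f"({_rigid_mode_name(fixed_dofs, nodes) if len(fixed_dofs) else 'all modes'})"
        )

    d = material.d_matrix()
    ke = _stiffness_batch(nodes[elements], d, thickness, order)

    edofs = np.empty((ne, 16), dtype=np.int64)
    edofs[:, 0::2] = elements * 2
    edofs[:, 1::2] = elements * 2 + 1
    rows = np.repeat(edofs, 16, axis=1).ravel()
    cols = np.tile(edofs, (1, 16)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsc()

    free = np.setdiff1d(np.arange(ndof), fixed_dofs, assume_unique=False)
    u = np.zeros(ndof)
    u[fixed_dofs] = fixed_vals
    rhs = forces.ravel()[free] - k[np.ix_(free, fixed_dofs)] @ fixed_vals
    if np.any(rhs) or np.any(fixed_vals):
        kff = k[np.ix_(free, free)]
        try:
            lu = spla.splu(kff.tocsc())
            uf = lu.solve(rhs)
        except RuntimeError as exc:  # singular factorisation
            raise SolverError(
                "singular system: free rigid-body mode "
                f"({_rigid_mode_name(fixed_dofs, nodes)})"
            ) from exc
        if not np.all(np.isfinite(uf)):
            raise SolverError(
                "singular system: free rigid-body mode "
                f"({_rigid_mode_name(fixed_dofs, nodes)})"
            )
        u[free] = uf

    # Reactions at constrained dofs: r = K u - f.
    resid = k @ u - forces.ravel()
    reactions = np.zeros(ndof)
    reactions[fixed_dofs] = resid[fixed_dofs]

    sx, sy, txy, vm = _recover_stresses(nodes, elements, u, d, order)
    return StressField(
        element_vm=vm,
        element_components=np.column_stack([sx, sy, txy]),
        nodal_displacements=u.reshape(nn, 2),
        reactions=reactions.reshape(nn, 2),
    )


def _recover_stresses(nodes, elements, u, d, order):
    dn, wts = _precompute_dn(order)
    coords = nodes[elements]
    jac, det = _jacobians(coords, dn)
    inv = np.linalg.inv(jac)
    grad = np.einsum("egab,gib->egia", inv, dn)
    ue = np.empty((elements.shape[0], 8, 2))
    ue[:, :, 0] = u.reshape(-1, 2)[elements, 0]
    ue[:, :, 1] = u.reshape(-1, 2)[elements, 1]
    ex = np.einsum("egi,ei->eg", grad[..., 0], ue[..., 0])
    ey = np.einsum("egi,ei->eg", grad[..., 1], ue[..., 1])
    gxy = np.einsum("egi,ei->eg", grad[..., 1], ue[..., 0]) + np.einsum(
        "egi,ei->eg", grad[..., 0], ue[..., 1]
    )
    strains = np.stack([ex, ey, gxy], axis=-1)  # (ne, g, 3)
    stresses = strains @ d.T  # (ne, g, 3)
    vm_gp = von_mises_plane_stress(
        stresses[..., 0], stresses[..., 1], stresses[..., 2]
    )
    w = det * wts[None, :]
    wtot = w.sum(axis=1)
    vm = (vm_gp * w).sum(axis=1) / wtot
    comp = (stresses * w[..., None]).sum(axis=1) / wtot[:, None]
    return comp[:, 0], comp[:, 1], comp[:, 2], vm


def solve_case(mesh, material: Material, thickness: float, load_case, order: int = 2) -> StressField:
    """Solve a bite-scenario :class:`~mandifem.loads.LoadCase`.

    The condyle node is fully fixed; the bite node is fixed only
    perpendicular to the occlusal plane (the y direction, the model being
    oriented with the occlusal plane along x), which generates the bite
    reaction force.
    """
    nn = np.asarray(mesh.nodes).shape[0]
    forces = np.zeros((nn, 2))
    for node, vec in load_case.muscle_forces:
        forces[node] += np.asarray(vec, dtype=float)
    fixed = {
        (int(load_case.condyle_node), 0): 0.0,
        (int(load_case.condyle_node), 1): 0.0,
        (int(load_case.bite_node), 1): 0.0,
    }
    return solve(mesh, material, thickness, forces, fixed, order=order)
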