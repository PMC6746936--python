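"""Linear-elastic plane-stress finite-element solver.

4-node bilinear quadrilaterals with 2x2 Gauss quadrature, sparse assembly,
grounded springs, prescribed (zero) displacements, and a rigid-link hinge:
a set of slave nodes moving rigidly with a master point whose translations
are fixed and whose in-plane rotation is the only free degree of freedom.
Constraints are applied by a transformation matrix (master-slave
elimination), so the reduced system stays symmetric positive definite.

Strains are evaluated at element centroids; principal strains are the
eigenvalues of the symmetric 2D strain tensor (eps_xy = gamma_xy / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

_GAUSS = 1.0 / np.sqrt(3.0)
_GPTS = [(-_GAUSS, -_GAUSS), (_GAUSS, -_GAUSS), (_GAUSS, _GAUSS), (-_GAUSS, _GAUSS)]


def _shape_grad(xi: float, eta: float) -> np.ndarray:
    """Derivatives of the 4 bilinear shape functions wrt (xi, eta): (4, 2)."""
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [+(1 - eta), -(1 + xi)],
            [+(1 + eta), +(1 + xi)],
            [-(1 + eta), +(1 - xi)],
        ]
    )


def plane_stress_d(e: float | np.ndarray, nu: float) -> np.ndarray:
    """Plane-stress constitutive matrix D (3x3), possibly batched over E."""
    base = np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    scale = np.asarray(e, dtype=float) / (1.0 - nu**2)
    if scale.ndim == 0:
        return scale * base
    return scale[:, None, None] * base


def _b_matrices(coords: np.ndarray, xi: float, eta: float):
    """Strain-displacement matrices at one parent point for all elements.

    coords: (M, 4, 2) element node coordinates.
    Returns B (M, 3, 8) and detJ (M,).
    """
    dN = _shape_grad(xi, eta)                      # (4, 2)
    jac = np.einsum("qa,mqb->mab", dN, coords)      # (M, 2, 2) J_ab = dx_b/dxi_a
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    dNdx = np.einsum("qa,mba->mqb", dN, inv)        # (M, 4, 2) dN/dx = J^-1 dN/dxi
    m = coords.shape[0]
    b = np.zeros((m, 3, 8))
    b[:, 0, 0::2] = dNdx[:, :, 0]
    b[:, 1, 1::2] = dNdx[:, :, 1]
    b[:, 2, 0::2] = dNdx[:, :, 1]
    b[:, 2, 1::2] = dNdx[:, :, 0]
    return b, det


def assemble_stiffness(
    nodes: np.ndarray,
    elements: np.ndarray,
    e_per_element: np.ndarray,
    nu: float,
    thickness: float,
) -> sp.csr_matrix:
    """Assemble the global sparse stiffness matrix (2 dofs per node)."""
    coords = nodes[elements]                        # (M, 4, 2)
    m = len(elements)
    if np.any(np.asarray(e_per_element) <= 0):
        bad = np.nonzero(np.asarray(e_per_element) <= 0)[0]
        raise ValueError(
            f"non-positive Young's modulus on elements {bad[:10].tolist()}"
        )
    d_unit = plane_stress_d(1.0, nu)
    ke = np.zeros((m, 8, 8))
    for xi, eta in _GPTS:
        b, det = _b_matrices(coords, xi, eta)
        if np.any(det <= 0):
            bad = np.nonzero(det <= 0)[0]
            raise ValueError(f"degenerate elements (det J <= 0): {bad[:10].tolist()}")
        ke += np.einsum("maf,ab,mbg->mfg", b, d_unit, b) * det[:, None, None]
    ke *= (np.asarray(e_per_element, dtype=float) * thickness)[:, None, None]

    edof = np.empty((m, 8), dtype=np.int64)
    edof[:, 0::2] = 2 * elements
    edof[:, 1::2] = 2 * elements + 1
    rows = np.repeat(edof, 8, axis=1).ravel()
    cols = np.tile(edof, (1, 8)).ravel()
    n_dof = 2 * len(nodes)
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return k.tocsr()


def centroid_strains(
    nodes: np.ndarray, elements: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Element-centroid strains (eps_xx, eps_yy, gamma_xy): (M, 3)."""
    coords = nodes[elements]
    b, _ = _b_matrices(coords, 0.0, 0.0)
    edof = np.empty((len(elements), 8), dtype=np.int64)
    edof[:, 0::2] = 2 * elements
    edof[:, 1::2] = 2 * elements + 1
    return np.einsum("mij,mj->mi", b, u[edof])


def principal_strains(strains: np.ndarray):
    """Principal strains (eps1 >= eps3) of 2D strain tensors.

    ``strains`` is (..., 3) as (eps_xx, eps_yy, gamma_xy); the tensor shear
    component is gamma/2.
    """
    s = np.asarray(strains, dtype=float)
    exx, eyy, gxy = s[..., 0], s[..., 1], s[..., 2]
    mean = 0.5 * (exx + eyy)
    radius = np.sqrt((0.5 * (exx - eyy)) ** 2 + (0.5 * gxy) ** 2)
    return mean + radius, mean - radius


def _solve_spd(k_red: sp.csc_matrix, f_red: np.ndarray) -> np.ndarray:
    """Solve the reduced SPD system: Jacobi-preconditioned CG, LU fallback.

    The reduced stiffness matrix is symmetric positive definite, so CG with
    a diagonal preconditioner converges quickly on these well-conditioned
    plate problems; a direct factorization backs it up.
    """
    diag = k_red.diagonal()
    if np.any(diag <= 0):
        raise ValueError(
            "non-positive-definite stiffness (non-positive diagonal); "
            f"offending dofs {np.nonzero(diag <= 0)[0][:10].tolist()}"
        )
    m = sp.diags(1.0 / diag)
    q, info = spla.cg(k_red, f_red, rtol=1e-13, atol=0.0, maxiter=20000, M=m)
    if info == 0 and np.all(np.isfinite(q)):
        return q
    try:
        q = spla.spsolve(k_red, f_red)
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise ValueError(f"singular system (insufficient constraints): {exc}")
    if not np.all(np.isfinite(q)):
        raise ValueError("singular system (insufficient constraints)")
    return q


@dataclass
class RigidHinge:
    """Slave nodes rigidly linked to a pinned master point free in rotation."""

    slave_nodes: np.ndarray     # node indices
    master_xy: np.ndarray       # (2,) master point, mm


@dataclass
class SolveResult:
    """Displacements, centroid strains and equilibrium diagnostics."""

    u: np.ndarray                   # (2*n_nodes,) nodal displacements, mm
    strains: np.ndarray             # (n_elem, 3) exx, eyy, gxy
    eps1: np.ndarray
    eps3: np.ndarray
    reaction: np.ndarray            # (2,) total constraint + spring force
    applied: np.ndarray             # (2,) total applied force
    equilibrium_residual: float     # |applied + reaction| / |applied|
    solver_residual: float          # reduced-system relative residual
    hinge_rotation: float = 0.0
    extras: dict = field(default_factory=dict)


def solve_plane_stress(
    nodes: np.ndarray,
    elements: np.ndarray,
    e_per_element: np.ndarray,
    nu: float,
    thickness: float,
    nodal_forces: np.ndarray,
    fixed_dofs: np.ndarray | None = None,
    spring_nodes: np.ndarray | None = None,
    spring_k_per_node: float = 0.0,
    hinge: RigidHinge | None = None,
) -> SolveResult:
    """Assemble and solve one plane-stress problem.

    Parameters
    ----------
    nodal_forces : (2*n_nodes,) external force vector, N (coordinates in mm,
        moduli in MPa, so forces are consistently in N).
    fixed_dofs : dof indices held at zero.
    spring_nodes : nodes grounded through isotropic springs of
        ``spring_k_per_node`` (N/mm) in each in-plane direction.
    hinge : optional rigid-link hinge (see :class:`RigidHinge`).
    """
    n_dof = 2 * len(nodes)
    has_springs = (
        spring_nodes is not None and len(spring_nodes) > 0 and spring_k_per_node > 0
    )
    has_fixed = fixed_dofs is not None and len(fixed_dofs) > 0
    if not (has_springs or has_fixed or hinge is not None):
        raise ValueError(
            "singular system (insufficient constraints): no fixed dofs, "
            "springs or hinge — rigid-body modes are unconstrained"
        )
    k = assemble_stiffness(nodes, elements, e_per_element, nu, thickness)

    spring_dofs = np.array([], dtype=np.int64)
    if spring_nodes is not None and len(spring_nodes) > 0 and spring_k_per_node > 0:
        spring_dofs = np.concatenate([2 * spring_nodes, 2 * spring_nodes + 1])
        k = k + sp.coo_matrix(
            (np.full(len(spring_dofs), spring_k_per_node), (spring_dofs, spring_dofs)),
            shape=(n_dof, n_dof),
        ).tocsr()

    fixed = np.asarray(fixed_dofs, dtype=np.int64) if fixed_dofs is not None else np.array([], dtype=np.int64)

    # transformation u = T q ; reduced coords = free dofs (+ hinge rotation)
    slave_dofs = np.array([], dtype=np.int64)
    t_rows, t_cols, t_vals = [], [], []
    free_mask = np.ones(n_dof, dtype=bool)
    free_mask[fixed] = False
    if hinge is not None:
        if len(hinge.slave_nodes) == 0:
            raise ValueError("hinge with no slave nodes")
        slave_dofs = np.concatenate(
            [2 * hinge.slave_nodes, 2 * hinge.slave_nodes + 1]
        )
        free_mask[slave_dofs] = False
    free_dofs = np.nonzero(free_mask)[0]
    n_red = len(free_dofs) + (1 if hinge is not None else 0)
    if n_red == 0:
        raise ValueError("no unconstrained degrees of freedom")
    t_rows.append(free_dofs)
    t_cols.append(np.arange(len(free_dofs)))
    t_vals.append(np.ones(len(free_dofs)))
    if hinge is not None:
        theta_col = len(free_dofs)
        xm, ym = hinge.master_xy
        xy = nodes[hinge.slave_nodes]
        # small-rotation rigid link: u = -theta*(y - ym), v = theta*(x - xm)
        t_rows.append(2 * hinge.slave_nodes)
        t_cols.append(np.full(len(hinge.slave_nodes), theta_col))
        t_vals.append(-(xy[:, 1] - ym))
        t_rows.append(2 * hinge.slave_nodes + 1)
        t_cols.append(np.full(len(hinge.slave_nodes), theta_col))
        t_vals.append(xy[:, 0] - xm)
    t = sp.coo_matrix(
        (
            np.concatenate(t_vals),
            (np.concatenate(t_rows), np.concatenate(t_cols)),
        ),
        shape=(n_dof, n_red),
    ).tocsr()

    f = np.asarray(nodal_forces, dtype=float)
    k_red = (t.T @ k @ t).tocsc()
    f_red = t.T @ f
    q = _solve_spd(k_red, f_red)
    kq = k_red @ q
    denom = max(float(np.linalg.norm(f_red)), 1e-30)
    solver_residual = float(np.linalg.norm(kq - f_red)) / denom

    u = t @ q
    strains = centroid_strains(nodes, elements, u)
    eps1, eps3 = principal_strains(strains)

    # reactions: residual K u - f on constrained dofs, plus spring forces
    resid = k @ u - f
    constrained = np.concatenate([fixed, slave_dofs])
    reaction = np.zeros(2)
    if len(constrained):
        reaction[0] += resid[constrained[constrained % 2 == 0]].sum()
        reaction[1] += resid[constrained[constrained % 2 == 1]].sum()
    if len(spring_dofs):
        reaction[0] -= spring_k_per_node * u[spring_dofs[spring_dofs % 2 == 0]].sum()
        reaction[1] -= spring_k_per_node * u[spring_dofs[spring_dofs % 2 == 1]].sum()
    applied = np.array([f[0::2].sum(), f[1::2].sum()])
    denom_f = max(float(np.linalg.norm(applied)), 1e-30)
    eq_res = float(np.linalg.norm(applied + reaction)) / denom_f

    return SolveResult(
        u=u,
        strains=strains,
        eps1=eps1,
        eps3=eps3,
        reaction=reaction,
        applied=applied,
        equilibrium_residual=eq_res,
        solver_residual=solver_residual,
        hinge_rotation=float(q[-1]) if hinge is not None else 0.0,
    )
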