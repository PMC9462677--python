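"""Small-strain linear elasticity on tet4/tet10 meshes.

Supports exactly the boundary-condition pattern of a spine-segment
compression test: the caudal end surface fully fixed, and the cranial
end surface rigidly tied to a pilot node whose translation and rotation
are prescribed (the remote-displacement / rigid MPC construction).
Constraints are enforced with Lagrange multipliers, so tied-node
kinematics are exact and reactions are read directly from the
multipliers.  Consistent units: mm, N, MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinematics import RigidTransform
from .mesh import TetMesh

__all__ = ["BoundaryConditions", "FESolution", "assemble", "apply_bcs_and_solve", "reaction"]

# 4-point second-order Gauss rule on the reference tet (barycentric)
_GAUSS_A = 0.5854101966249685
_GAUSS_B = 0.1381966011250105
_GAUSS_PTS = np.array([
    [_GAUSS_A, _GAUSS_B, _GAUSS_B, _GAUSS_B],
    [_GAUSS_B, _GAUSS_A, _GAUSS_B, _GAUSS_B],
    [_GAUSS_B, _GAUSS_B, _GAUSS_A, _GAUSS_B],
    [_GAUSS_B, _GAUSS_B, _GAUSS_B, _GAUSS_A],
])
_GAUSS_W = np.full(4, 0.25)


def _shape_gradients(order: int, bary: np.ndarray) -> np.ndarray:
    """d N_i / d (xi, eta, zeta) at a barycentric point.

    Natural coordinates: L1 = xi, L2 = eta, L3 = zeta, L0 = 1 - xi - eta - zeta.
    Returns (n_nodes, 3).
    """
    l0, l1, l2, l3 = bary
    # dL/d(xi,eta,zeta): L0 -> (-1,-1,-1); L1 -> (1,0,0); L2 -> (0,1,0); L3 -> (0,0,1)
    dl = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    if order == 4:
        return dl.copy()
    l = np.array([l0, l1, l2, l3])
    g = np.zeros((10, 3))
    for i in range(4):
        g[i] = (4.0 * l[i] - 1.0) * dl[i]
    from .mesh import TET10_EDGES
    for k, (a, b) in enumerate(TET10_EDGES):
        g[4 + k] = 4.0 * (l[a] * dl[b] + l[b] * dl[a])
    return g


def _elasticity_matrices(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic 6x6 constitutive matrices (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    ne = E.shape[0]
    d = np.zeros((ne, 6, 6))
    for i in range(3):
        for j in range(3):
            d[:, i, j] = lam
        d[:, i, i] = lam + 2 * mu
    for i in range(3, 6):
        d[:, i, i] = mu
    return d


def _b_matrices(mesh: TetMesh, bary: np.ndarray):
    """Strain-displacement operators at one barycentric point for all elements.

    Returns (B, detJ): B is (E, 6, 3*order); detJ per element.
    """
    order = mesh.order
    dn = _shape_gradients(order, bary)                      # (n, 3) in natural coords
    x = mesh.nodes[mesh.elements]                           # (E, n, 3)
    jac = np.einsum("eni,nj->eij", x, dn)                   # dx/dxi, (E, 3, 3)
    detj = np.linalg.det(jac)
    inv = np.linalg.inv(jac)
    gradx = np.einsum("nj,eji->eni", dn, inv)               # dN/dx, (E, n, 3)
    ne, n, _ = gradx.shape
    b = np.zeros((ne, 6, 3 * n))
    b[:, 0, 0::3] = gradx[:, :, 0]
    b[:, 1, 1::3] = gradx[:, :, 1]
    b[:, 2, 2::3] = gradx[:, :, 2]
    b[:, 3, 0::3] = gradx[:, :, 1]
    b[:, 3, 1::3] = gradx[:, :, 0]
    b[:, 4, 1::3] = gradx[:, :, 2]
    b[:, 4, 2::3] = gradx[:, :, 1]
    b[:, 5, 0::3] = gradx[:, :, 2]
    b[:, 5, 2::3] = gradx[:, :, 0]
    return b, detj


def assemble(mesh: TetMesh) -> sp.csr_matrix:
    """Global stiffness matrix (3N x 3N, symmetric CSR).

    Standard isoparametric assembly with a 4-point Gauss rule (exact for
    straight-sided tet10).  Raises on inverted elements.
    """
    if mesh.E is None or mesh.nu is None:
        raise ValueError("mesh has no material assignment; run map_materials first")
    vols = mesh.volumes()
    bad = np.where(vols <= 0)[0]
    if bad.size:
        raise ValueError(f"inverted element(s): {bad[:10].tolist()}")
    d = _elasticity_matrices(mesh.E, mesh.nu)
    order = mesh.order
    ndof_e = 3 * order
    ne = mesh.n_elements
    ke = np.zeros((ne, ndof_e, ndof_e))
    npts = 1 if order == 4 else 4
    for g in range(npts):
        bary = _GAUSS_PTS[g] if order == 10 else np.array([0.25, 0.25, 0.25, 0.25])
        w = _GAUSS_W[g] if order == 10 else 1.0
        b, detj = _b_matrices(mesh, bary)
        # detJ of the natural->physical map; reference tet volume = 1/6
        scale = w * detj / 6.0
        db = np.einsum("eij,ejk->eik", d, b)
        ke += np.einsum("eji,ejk,e->eik", b, db, scale)

    edofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, ndof_e)
    rows = np.repeat(edofs, ndof_e, axis=1).ravel()
    cols = np.tile(edofs, (1, ndof_e)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes,) * 2)
    k = k.tocsr()
    return 0.5 * (k + k.T)  # symmetrize away assembly round-off


@dataclass
class BoundaryConditions:
    """Fixed base + rigid pilot tie, mirroring the experimental mounting."""

    fixed_nodes: np.ndarray
    tied_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pilot: np.ndarray | None = None                 # SP coordinates, mm
    pilot_motion: RigidTransform | None = None
    target_axial_force: float | None = None         # N
    axial_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.tied_nodes = np.asarray(self.tied_nodes, dtype=np.int64)
        self.axial_dir = np.asarray(self.axial_dir, float)
        self.axial_dir = self.axial_dir / np.linalg.norm(self.axial_dir)
        if np.intersect1d(self.fixed_nodes, self.tied_nodes).size:
            raise ValueError("fixed and tied node sets must be disjoint")
        if self.pilot_motion is not None and self.tied_nodes.size == 0:
            raise ValueError("pilot motion prescribed but the tied node set is empty")
        if self.pilot is not None:
            self.pilot = np.asarray(self.pilot, float).reshape(3)


@dataclass
class FESolution:
    """Displacements, reactions and element strain/stress of one solve."""

    mesh: TetMesh
    u: np.ndarray                       # (N, 3) mm
    constraint_forces: dict             # node id -> (3,) force N exerted BY the support
    fixed_nodes: np.ndarray
    tied_nodes: np.ndarray
    axial_dir: np.ndarray
    strain: np.ndarray                  # (E, 6) engineering, element centroid
    stress: np.ndarray                  # (E, 6) MPa

    @property
    def reaction_force(self) -> np.ndarray:
        """Total reaction at the fixed (base) set, N."""
        return reaction(self, self.fixed_nodes)[0]

    @property
    def axial_resultant(self) -> float:
        """Base reaction component along the axial direction, N."""
        return float(self.reaction_force @ self.axial_dir)


def _tied_node_targets(mesh: TetMesh, bcs: BoundaryConditions) -> np.ndarray:
    """Prescribed displacement of each tied node under the pilot motion.

    u_i = R (x_i - SP) + T - (x_i - SP): the full (not linearized)
    rigid-body motion of the pilot carried to the tied surface.
    """
    motion = bcs.pilot_motion
    rot = np.asarray(motion.rotation, float)
    if np.abs(rot.T @ rot - np.eye(3)).max() > 1e-6:
        raise ValueError("pilot rotation is not orthonormal (tolerance 1e-6)")
    x = mesh.nodes[bcs.tied_nodes]
    rel = x - bcs.pilot
    t_sp = motion.apply(bcs.pilot) - bcs.pilot   # translation re-expressed about SP
    return rel @ rot.T + t_sp - rel


def apply_bcs_and_solve(mesh: TetMesh, bcs: BoundaryConditions,
                        k: sp.csr_matrix | None = None) -> FESolution:
    """Solve the constrained system and return displacements + reactions.

    Both constraint sets (fixed base, rigid pilot tie) prescribe every
    dof they touch, so the constraints C u = g are enforced exactly by
    reducing to the free dofs (K_ff u_f = -K_fc g) and factorizing the
    SPD reduced operator; this is algebraically identical to the
    Lagrange-multiplier form of the same constraints, and the reaction at
    a constrained dof equals the multiplier, recovered here as the
    stiffness residual (K u) on the constrained rows.
    """
    if k is None:
        k = assemble(mesh)
    ndof = 3 * mesh.n_nodes

    con_nodes = [bcs.fixed_nodes]
    con_vals = [np.zeros((bcs.fixed_nodes.size, 3))]
    if bcs.pilot_motion is not None:
        if bcs.pilot is None:
            raise ValueError("pilot coordinates required with a pilot motion")
        con_nodes.append(bcs.tied_nodes)
        con_vals.append(_tied_node_targets(mesh, bcs))
    nodes_c = np.concatenate(con_nodes)
    vals_c = np.vstack(con_vals)
    if nodes_c.size == 0:
        raise ValueError("no constraints: the system is singular")

    cdofs = (3 * nodes_c[:, None] + np.arange(3)[None, :]).ravel()
    g = vals_c.ravel()
    free = np.setdiff1d(np.arange(ndof), cdofs)

    u_full = np.zeros(ndof)
    u_full[cdofs] = g
    k_csc = k.tocsc()
    rhs = -(k_csc[:, cdofs] @ g)[free]
    k_ff = k_csc[free][:, free]
    try:
        lu = spla.splu(k_ff.tocsc(), permc_spec="MMD_AT_PLUS_A",
                       options={"SymmetricMode": True})
        u_f = lu.solve(rhs)
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(
            f"singular constrained system (insufficient constraints?): {exc}"
        ) from exc
    if not np.all(np.isfinite(u_f)):
        raise np.linalg.LinAlgError("singular constrained system (insufficient constraints?)")
    u_full[free] = u_f
    u = u_full.reshape(-1, 3)

    # support force on the structure at a constrained dof = (K u) there
    forces = (k @ u_full)[cdofs].reshape(-1, 3)
    constraint_forces = {int(n): forces[i] for i, n in enumerate(nodes_c)}

    strain, stress = _element_fields(mesh, u)
    return FESolution(mesh, u, constraint_forces, bcs.fixed_nodes,
                      bcs.tied_nodes, bcs.axial_dir, strain, stress)


def _element_fields(mesh: TetMesh, u: np.ndarray):
    """Centroid strain and stress per element."""
    bary = np.array([0.25, 0.25, 0.25, 0.25])
    b, _ = _b_matrices(mesh, bary)
    ue = u[mesh.elements].reshape(mesh.n_elements, -1)
    strain = np.einsum("eij,ej->ei", b, ue)
    d = _elasticity_matrices(mesh.E, mesh.nu)
    stress = np.einsum("eij,ej->ei", d, strain)
    return strain, stress


def reaction(solution: FESolution, node_set, about=None):
    """Total constraint force (N) and moment (N·mm) over a node set.

    ``about`` is the moment reference point (defaults to the origin).
    Raises if any node in the set was not constrained in the solve.
    """
    node_set = np.asarray(node_set, dtype=np.int64)
    missing = [int(n) for n in node_set if int(n) not in solution.constraint_forces]
    if missing:
        raise ValueError(f"nodes not constrained in this solution: {missing[:5]}")
    if about is None:
        about = np.zeros(3)
    about = np.asarray(about, float)
    force = np.zeros(3)
    moment = np.zeros(3)
    for n in node_set:
        f = solution.constraint_forces[int(n)]
        force += f
        moment += np.cross(solution.mesh.nodes[n] - about, f)
    return force, moment


def equilibrium_residual(solution: FESolution) -> float:
    """|sum of all constraint forces| / max nodal constraint force."""
    total = np.zeros(3)
    fmax = 0.0
    for f in solution.constraint_forces.values():
        total += f
        fmax = max(fmax, float(np.linalg.norm(f)))
    return float(np.linalg.norm(total) / fmax) if fmax > 0 else 0.0
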