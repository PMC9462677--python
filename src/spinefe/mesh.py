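"""Tetrahedral mesh container and simple structured meshers.

Meshes are tet4 or tet10 (corner-first connectivity; midside node k+4
sits on the edge between corners given by ``TET10_EDGES[k]``).  Element
sets carry the anatomical labelling (``bone_L1`` ... ``bone_L4``,
``disc_1`` ... ``disc_3``) the downstream stages rely on.
Units are mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TetMesh", "box_mesh", "cylinder_stack_mesh", "TET10_EDGES"]

# edge -> (corner, corner) for the 6 midside nodes of a tet10
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

# local corner offsets of a hexahedron, VTK ordering
_HEX_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
     (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
)

# corner-node triangles of a tet's 4 faces (outward for positive volume)
_TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))


@dataclass
class TetMesh:
    nodes: np.ndarray                      # (N, 3) mm
    elements: np.ndarray                   # (E, 4) or (E, 10) int
    element_sets: dict = field(default_factory=dict)
    E: np.ndarray | None = None            # MPa, per element
    nu: np.ndarray | None = None           # per element

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise ValueError("elements must be (E, 4) or (E, 10)")

    @property
    def order(self) -> int:
        """Nodes per element: 4 (linear) or 10 (quadratic)."""
        return self.elements.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def volumes(self) -> np.ndarray:
        """Signed corner-tet volumes (positive for valid elements)."""
        v = self.nodes[self.elements[:, :4]]
        return np.linalg.det(v[:, 1:] - v[:, :1]) / 6.0

    def validate(self, midside_tol: float = 1e-9) -> None:
        """Raise if any Jacobian is non-positive, a node is orphaned, or a
        tet10 midside node is off its edge midpoint by more than ``midside_tol``."""
        vols = self.volumes()
        bad = np.where(vols <= 0)[0]
        if bad.size:
            raise ValueError(f"non-positive Jacobian in elements {bad[:10].tolist()}")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise ValueError(f"{int((~used).sum())} nodes not referenced by any element")
        if self.order == 10:
            for k, (a, b) in enumerate(TET10_EDGES):
                mid = 0.5 * (self.nodes[self.elements[:, a]] + self.nodes[self.elements[:, b]])
                err = np.abs(self.nodes[self.elements[:, 4 + k]] - mid).max()
                if err > midside_tol:
                    raise ValueError(f"midside node off edge midpoint by {err:.2e} mm")

    def disc_mask(self) -> np.ndarray:
        """Boolean per-element mask of disc elements (sets named disc_*)."""
        mask = np.zeros(self.n_elements, dtype=bool)
        for name, ids in self.element_sets.items():
            if name.startswith("disc"):
                mask[np.asarray(ids)] = True
        return mask

    def surface_faces(self) -> np.ndarray:
        """Boundary corner-triangles (F, 3), outward oriented."""
        faces = self.elements[:, :4][:, _TET_FACES]   # (E, 4, 3)
        flat = faces.reshape(-1, 3)
        key = np.sort(flat, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return flat[counts[inv] == 1]

    def surface_nodes(self) -> np.ndarray:
        """Ids of nodes on the boundary surface (corner nodes only)."""
        return np.unique(self.surface_faces())

    def to_tet10(self) -> "TetMesh":
        """Promote a tet4 mesh to tet10 by inserting edge-midpoint nodes."""
        if self.order == 10:
            return self
        edges = self.elements[:, TET10_EDGES]            # (E, 6, 2)
        flat = np.sort(edges.reshape(-1, 2), axis=1)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        mid_nodes = 0.5 * (self.nodes[uniq[:, 0]] + self.nodes[uniq[:, 1]])
        new_nodes = np.vstack([self.nodes, mid_nodes])
        mid_ids = self.n_nodes + inv.reshape(self.n_elements, 6)
        elements = np.hstack([self.elements, mid_ids])
        return TetMesh(new_nodes, elements, dict(self.element_sets),
                       None if self.E is None else self.E.copy(),
                       None if self.nu is None else self.nu.copy())

    def refine(self) -> "TetMesh":
        """Uniform refinement: each tet4 split into 8 children via edge midpoints.

        The children are the 4 corner tets plus a 4-way split of the inner
        octahedron; the domain is exactly preserved (nested meshes), so a
        refinement study isolates discretization error from geometry.
        Element sets and materials are inherited child-from-parent.
        Call on a tet4 mesh (promote with :meth:`to_tet10` afterwards).
        """
        if self.order != 4:
            raise ValueError("refine the tet4 parent, then promote to tet10")
        edges = self.elements[:, TET10_EDGES]
        flat = np.sort(edges.reshape(-1, 2), axis=1)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        mids = self.n_nodes + inv.reshape(self.n_elements, 6)
        nodes = np.vstack([self.nodes, 0.5 * (self.nodes[uniq[:, 0]] + self.nodes[uniq[:, 1]])])
        v = self.elements
        m01, m12, m02, m03, m13, m23 = (mids[:, k] for k in range(6))
        children = np.stack([
            np.column_stack([v[:, 0], m01, m02, m03]),
            np.column_stack([v[:, 1], m12, m01, m13]),
            np.column_stack([v[:, 2], m02, m12, m23]),
            np.column_stack([v[:, 3], m03, m13, m23]),
            # inner octahedron, split through the m01-m23 diagonal
            np.column_stack([m01, m12, m02, m23]),
            np.column_stack([m01, m02, m03, m23]),
            np.column_stack([m01, m03, m13, m23]),
            np.column_stack([m01, m13, m12, m23]),
        ], axis=1).reshape(-1, 4)
        vols = np.linalg.det(nodes[children][:, 1:] - nodes[children][:, :1])
        flip = vols < 0
        children[flip, 0], children[flip, 1] = children[flip, 1], children[flip, 0].copy()
        sets = {name: (8 * np.asarray(ids)[:, None] + np.arange(8)).ravel()
                for name, ids in self.element_sets.items()}
        e = None if self.E is None else np.repeat(self.E, 8)
        nu = None if self.nu is None else np.repeat(self.nu, 8)
        return TetMesh(nodes, children, sets, e, nu)

    def nodes_in_set(self, set_name: str) -> np.ndarray:
        """All node ids referenced by the elements of a named set."""
        ids = np.asarray(self.element_sets[set_name])
        return np.unique(self.elements[ids].ravel())


# permutation-path (Kuhn) subdivision of a hex into 6 conforming tets
_KUHN_PATHS = []
import itertools as _it
for _perm in _it.permutations(range(3)):
    _steps = np.zeros((4, 3), dtype=int)
    for _k, _axis in enumerate(_perm):
        _steps[_k + 1] = _steps[_k]
        _steps[_k + 1, _axis] += 1
    _KUHN_PATHS.append(_steps)
_KUHN_PATHS = np.array(_KUHN_PATHS)  # (6, 4, 3) corner offsets


def _hexes_to_tets(node_id, hex_ijk):
    """Split structured hexes (given by their low-corner (i,j,k)) into 6 tets."""
    tets = []
    for steps in _KUHN_PATHS:
        corners = hex_ijk[:, None, :] + steps[None, :, :]     # (H, 4, 3)
        tets.append(node_id[corners[..., 0], corners[..., 1], corners[..., 2]])
    out = np.stack(tets, axis=1).reshape(-1, 4)               # hex-major order
    return out


def _fix_orientation(nodes, tets):
    v = nodes[tets]
    vol = np.linalg.det(v[:, 1:] - v[:, :1])
    flip = vol < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    return tets


def box_mesh(lengths=(10.0, 10.0, 10.0), edge: float = 2.0, order: int = 4,
             origin=(0.0, 0.0, 0.0)) -> TetMesh:
    """Structured tet mesh of an axis-aligned box (for verification tests)."""
    lengths = np.asarray(lengths, float)
    n = np.maximum(1, np.round(lengths / edge).astype(int))
    axes = [origin[k] + np.linspace(0, lengths[k], n[k] + 1) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    node_id = np.arange(nodes.shape[0]).reshape(n[0] + 1, n[1] + 1, n[2] + 1)
    ijk = np.array(list(np.ndindex(n[0], n[1], n[2])))
    tets = _fix_orientation(nodes, _hexes_to_tets(node_id, ijk))
    mesh = TetMesh(nodes, tets, {"all": np.arange(tets.shape[0])})
    return mesh.to_tet10() if order == 10 else mesh


def _disc_section(radius: float, edge: float):
    """Structured node layout of a disc: elliptical mapping of a square grid.

    Returns (points2d, quad index grid shape) — a (m+1)^2 lattice mapped so
    the square boundary lands on the circle of ``radius``.
    """
    m = max(4, int(np.ceil(2.0 * radius / edge)))
    u = np.linspace(-1.0, 1.0, m + 1)
    U, V = np.meshgrid(u, u, indexing="ij")
    x = radius * U * np.sqrt(1.0 - V * V / 2.0)
    y = radius * V * np.sqrt(1.0 - U * U / 2.0)
    return x, y, m


def cylinder_stack_mesh(radius: float, layers: list[tuple[str, float]],
                        edge: float = 2.0, order: int = 10,
                        center=(0.0, 0.0)) -> TetMesh:
    """Tet mesh of a stack of coaxial cylinders (z axis), one named element
    set per layer.

    ``layers`` is a list of (set_name, height_mm) from bottom to top; layers
    sharing a name are merged into one set.  The cross-section is a smooth
    elliptical mapping of a square grid, so all Jacobians are positive and
    the mesh is conforming across layers.
    """
    x2d, y2d, m = _disc_section(radius, edge)
    z_bounds = [0.0]
    layer_rows: list[tuple[str, int]] = []
    for name, h in layers:
        if h <= 0:
            raise ValueError(f"layer {name!r} has non-positive height {h}")
        nsub = max(1, int(np.round(h / edge)))
        zs = np.linspace(z_bounds[-1], z_bounds[-1] + h, nsub + 1)[1:]
        z_bounds.extend(zs.tolist())
        layer_rows.extend([(name, 0)] * nsub)
    z = np.array(z_bounds)
    nz = len(z) - 1

    nodes = np.empty(((m + 1) * (m + 1) * (nz + 1), 3))
    npl = (m + 1) * (m + 1)  # nodes per level
    for k in range(nz + 1):
        sl = slice(k * npl, (k + 1) * npl)
        nodes[sl, 0] = x2d.ravel() + center[0]
        nodes[sl, 1] = y2d.ravel() + center[1]
        nodes[sl, 2] = z[k]
    node_id = (np.arange(npl).reshape(m + 1, m + 1)[:, :, None]
               + npl * np.arange(nz + 1)[None, None, :])

    ijk = np.array(list(np.ndindex(m, m, nz)))
    tets = _fix_orientation(nodes, _hexes_to_tets(node_id, ijk))

    # 6 tets per hex, hexes ordered with k fastest -> map element to layer
    hex_layer = ijk[:, 2]
    elem_layer = np.repeat(hex_layer, 6)  # tets are hex-major, 6 per hex
    sets: dict[str, list] = {}
    names = [name for name, _ in layer_rows]
    for e, lay in enumerate(elem_layer):
        sets.setdefault(names[lay], []).append(e)
    element_sets = {k: np.array(v, dtype=np.int64) for k, v in sets.items()}

    mesh = TetMesh(nodes, tets, element_sets)
    return mesh.to_tet10() if order == 10 else mesh
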