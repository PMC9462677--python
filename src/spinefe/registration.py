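"""Alignment of measured surface point clouds to the FE mesh surface.

The optical (DIC) system reports the vertebral surface as a point cloud
with per-point displacement vectors in its own frame.  Before any
comparison the cloud is rigidly registered onto the model surface; the
resulting transform maps points by x -> R x + t while displacement
vectors are rotated only.  Registration error is summarized both against
the nearest surface *node* (the convention used for the reported RMSE)
and the nearest point anywhere on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree

from .kinematics import RigidTransform, extract_rigid_motion
from .mesh import TetMesh

__all__ = [
    "SurfaceField",
    "RegistrationResult",
    "triangulate_cloud",
    "register_rigid",
    "apply_transform",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class SurfaceField:
    """Surface point cloud with per-point displacement vectors (mm)."""

    points: np.ndarray             # (P, 3) reference configuration
    displacements: np.ndarray      # (P, 3)
    roi_label: str = "custom"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.displacements = np.asarray(self.displacements, float)
        if self.points.shape != self.displacements.shape:
            raise ValueError("points and displacements must have matching shapes")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")


@dataclass
class RegistrationResult:
    transform: RigidTransform          # maps moving cloud into the model frame
    node_distances: np.ndarray         # per-point distance to nearest surface node, mm
    surface_distances: np.ndarray      # per-point distance to nearest surface point, mm
    mean_distance: float               # mean node distance, mm
    rmse: float                        # RMS node distance, mm (the reported metric)
    max_distance: float
    surface_rmse: float
    n_iterations: int
    converged: bool
    trace: list = field(default_factory=list)


def _median_spacing(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))


def triangulate_cloud(points: np.ndarray, edge_cutoff: float | None = None,
                      foldover_tol: float = 0.05) -> trimesh.Trimesh:
    """Open triangulated surface from a (roughly height-field) point cloud.

    The cloud is parameterized over its best-fit plane, Delaunay
    triangulated in 2D and lifted back to 3D.  Triangles with an edge
    longer than ``edge_cutoff`` (default 3x the median point spacing) are
    dropped, which trims the convex-hull bridges across concave outlines.
    """
    points = np.asarray(points, float)
    if points.shape[0] < 3:
        raise ValueError("at least 3 points are required for a surface")
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    in_plane, normal = vt[:2], vt[2]
    uv = (points - centroid) @ in_plane.T
    tri = Delaunay(uv)
    faces = tri.simplices
    if edge_cutoff is None:
        edge_cutoff = 3.0 * _median_spacing(points)
    edges = points[faces] - points[np.roll(faces, 1, axis=1)]
    longest = np.linalg.norm(edges, axis=2).max(axis=1)
    n_total = faces.shape[0]
    faces = faces[longest <= edge_cutoff]
    if faces.shape[0] < 0.5 * n_total:
        # trimming concave-outline bridges removes a few triangles; losing
        # the majority means the cloud piles up in the projection
        raise ValueError(
            "cloud is not projectable onto a plane (most triangles collapse "
            "in the parameterization); split the region of interest and retry"
        )
    # fold-over: lifted faces whose normal opposes the fit plane normal
    v = points[faces]
    face_n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    flipped = (face_n @ normal) < 0
    frac = flipped.mean()
    if min(frac, 1 - frac) > foldover_tol:
        raise ValueError(
            f"cloud is not projectable onto a plane ({min(frac, 1 - frac):.0%} "
            "folded triangles); split the region of interest and retry"
        )
    return trimesh.Trimesh(vertices=points, faces=faces, process=False)


def _closest_on_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query (vectorized, Ericson).

    ``tri``: (n, k, 3, 3) candidate triangles per query; ``p``: (n, 3).
    Returns (n, k, 3) closest points.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = p[:, None, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i", ab, ap)
    d2 = np.einsum("...i,...i", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i", ab, bp)
    d4 = np.einsum("...i,...i", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i", ab, cp)
    d6 = np.einsum("...i,...i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    out = a + v_face[..., None] * ab + w_face[..., None] * ac       # interior
    # order matters: later assignments win for the vertex/edge regions
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(on_bc[..., None], b + np.clip(w_bc, 0, 1)[..., None] * (c - b), out)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(on_ac[..., None], a + np.clip(w_ac, 0, 1)[..., None] * ac, out)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(on_ab[..., None], a + np.clip(v_ab, 0, 1)[..., None] * ab, out)
    vert_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(vert_a[..., None], a, out)
    vert_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(vert_b[..., None], b, out)
    vert_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(vert_c[..., None], c, out)
    return out


class _SurfaceQuery:
    """Nearest-point-on-surface queries against a triangulated boundary.

    Candidate faces come from a KD-tree over face centroids (k nearest);
    the exact closest point is then computed per candidate triangle.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 12):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, int)
        self.k = min(k, self.faces.shape[0])
        self._centroid_tree = cKDTree(self.vertices[self.faces].mean(axis=1))

    def query(self, points: np.ndarray):
        points = np.asarray(points, float)
        _, cand = self._centroid_tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        tri = self.vertices[self.faces[cand]]            # (n, k, 3, 3)
        closest = _closest_on_triangles(tri, points)
        d2 = np.sum((closest - points[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        idx = np.arange(points.shape[0])
        return closest[idx, best], np.sqrt(d2[idx, best])


def register_rigid(moving, fixed: TetMesh, init: RigidTransform | None = None,
                   max_iter: int = 100, tol: float = 1e-6) -> RegistrationResult:
    """Rigidly align a cloud (or SurfaceField) to the FE mesh surface.

    Iterative closest point from ``init`` (identity by default): each
    sweep matches every moving point to its nearest point on the surface
    triangulation and refits the rigid transform in closed form; stops
    when the surface RMS distance changes by less than ``tol`` mm.
    Deterministic for fixed inputs.
    """
    points = moving.points if isinstance(moving, SurfaceField) else np.asarray(moving, float)
    if init is None:
        init = RigidTransform.identity()
    surf = _SurfaceQuery(fixed.nodes, fixed.surface_faces())
    node_ids = fixed.surface_nodes()
    node_coords = fixed.nodes[node_ids]
    node_tree = cKDTree(node_coords)

    def corr_surface(cur):
        return surf.query(cur)

    def corr_nodes(cur):
        d, j = node_tree.query(cur)
        return node_coords[j], d

    # Phase 1: point-to-surface sweeps (robust); phase 2: nearest-node
    # correspondences, which remove the tangential sliding a smooth,
    # nearly symmetric surface leaves unconstrained and snap exactly when
    # the cloud samples the surface nodes themselves.
    transform = init
    trace: list[float] = []
    converged = False
    it = 0
    for corr, cap in ((corr_surface, max_iter // 2), (corr_nodes, max_iter)):
        prev = np.inf
        phase_done = False
        while it < cap and not phase_done:
            it += 1
            cur = transform.apply(points)
            closest, dist = corr(cur)
            rms = float(np.sqrt(np.mean(dist ** 2)))
            trace.append(rms)
            if abs(prev - rms) < tol:
                phase_done = True
                break
            prev = rms
            transform, _ = extract_rigid_motion(points, closest, about=np.zeros(3))
        converged = phase_done
    if not converged:
        raise ConvergenceError(
            f"ICP did not converge in {max_iter} iterations (last rmse {trace[-1]:.3g} mm)",
            trace,
        )
    final = transform.apply(points)
    _, sdist = surf.query(final)
    ndist, _ = node_tree.query(final)
    return RegistrationResult(
        transform=transform,
        node_distances=ndist,
        surface_distances=sdist,
        mean_distance=float(ndist.mean()),
        rmse=float(np.sqrt(np.mean(ndist ** 2))),
        max_distance=float(ndist.max()),
        surface_rmse=float(np.sqrt(np.mean(sdist ** 2))),
        n_iterations=it,
        converged=converged,
        trace=trace,
    )


def apply_transform(fld: SurfaceField, t: RigidTransform) -> SurfaceField:
    """Map a surface field into another frame.

    Point coordinates transform fully (rotation + translation);
    displacement vectors are rotated only — they are differences of
    positions and therefore translation-invariant.
    """
    return replace(
        fld,
        points=t.apply(fld.points),
        displacements=t.rotate_vectors(fld.displacements),
    )


def pca_init(moving: np.ndarray, fixed_points: np.ndarray) -> RigidTransform:
    """Coarse initial alignment: centroids + principal axes.

    Axis signs are disambiguated by trying the four proper-rotation sign
    combinations and keeping the one with the smallest RMS distance.
    """
    moving = np.asarray(moving, float)
    fixed_points = np.asarray(fixed_points, float)
    cm, cf = moving.mean(axis=0), fixed_points.mean(axis=0)
    _, _, vm = np.linalg.svd(moving - cm, full_matrices=False)
    _, _, vf = np.linalg.svd(fixed_points - cf, full_matrices=False)
    tree = cKDTree(fixed_points)
    best = None
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        s = np.diag([sx, sy, sx * sy])
        r = vf.T @ s @ vm
        if np.linalg.det(r) < 0:
            r = vf.T @ (s @ np.diag([1, 1, -1])) @ vm
        t = cf - r @ cm
        cand = RigidTransform(r, t)
        d, _ = tree.query(cand.apply(moving))
        score = float(np.sqrt(np.mean(d ** 2)))
        if best is None or score < best[0]:
            best = (score, cand)
    return best[1]
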