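"""Rigid-body transforms and marker-cluster motion extraction.

The motion of the loading pots is tracked through small clusters of
optical markers; the rigid transform that best aligns the reference and
deformed marker positions (in the least-squares sense) is recovered with
the SVD (Kabsch) algorithm, with the usual determinant guard so a proper
rotation is always returned.  Transforms are stored about an explicit
reference point to avoid the classic about-the-origin ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "MarkerCluster", "extract_rigid_motion", "pilot_point"]


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ (x - about) + about + t.

    ``about`` is the point the translation is expressed about; for pot
    motion this is the marker-cluster centroid (the pilot point SP).
    """

    rotation: np.ndarray
    translation: np.ndarray
    about: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        object.__setattr__(self, "about", np.asarray(self.about, float).reshape(3))

    def check(self, tol: float = 1e-9) -> "RigidTransform":
        """Raise unless the rotation is orthonormal with det +1."""
        r = self.rotation
        if np.abs(r.T @ r - np.eye(3)).max() > tol:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > tol:
            raise ValueError("rotation matrix must have determinant +1")
        return self

    @classmethod
    def identity(cls, about=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(about, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        out = (p - self.about) @ self.rotation.T + self.about + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def rotate_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Transform direction/displacement vectors (rotation only)."""
        return np.asarray(vectors, float) @ self.rotation.T

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """u(x) = R (x - about) + about + t - x for each point."""
        return self.apply(points) - np.asarray(points, float)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first), reported about the origin."""
        r = self.rotation @ other.rotation
        t = self.apply(other.apply(np.zeros(3)))
        return RigidTransform(r, t, np.zeros(3))

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        t = -r @ self.apply(np.zeros(3))
        return RigidTransform(r, t, np.zeros(3))

    def about_point(self, point) -> "RigidTransform":
        """Re-express the same mapping about a different reference point."""
        point = np.asarray(point, float).reshape(3)
        t = self.apply(point) - point
        return RigidTransform(self.rotation, t, point)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (about-origin form)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.apply(np.zeros(3))
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3], np.zeros(3))


@dataclass
class MarkerCluster:
    """Optical markers on a loading pot: reference and deformed positions."""

    ids: np.ndarray
    reference: np.ndarray          # (M, 3) mm
    deformed: np.ndarray           # (M, 3) mm, one tracked frame

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.reference = np.asarray(self.reference, float)
        self.deformed = np.asarray(self.deformed, float)
        if self.reference.shape != self.deformed.shape:
            raise ValueError("reference and deformed marker arrays differ in shape")


def pilot_point(cluster: MarkerCluster) -> np.ndarray:
    """Centroid of the reference marker positions (the pilot point SP)."""
    if cluster.reference.shape[0] < 1:
        raise ValueError("marker cluster is empty")
    return cluster.reference.mean(axis=0)


def extract_rigid_motion(ref: np.ndarray, deformed: np.ndarray,
                         about=None) -> tuple[RigidTransform, float]:
    """Least-squares rigid motion between corresponded point sets (Kabsch).

    Returns the transform (expressed about ``about``; defaults to the
    reference centroid) and the RMS residual of the fit in mm.  The
    smallest singular direction is sign-flipped when the raw SVD solution
    would be a reflection, so the result is always a proper rotation.
    """
    ref = np.asarray(ref, float)
    deformed = np.asarray(deformed, float)
    if ref.shape != deformed.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must both be (M, 3) with equal M")
    m = ref.shape[0]
    if m < 3:
        raise ValueError("at least 3 markers are required to recover a rotation")
    c_ref = ref.mean(axis=0)
    c_def = deformed.mean(axis=0)
    a = ref - c_ref
    b = deformed - c_def
    extents = np.linalg.svd(a, compute_uv=False)
    if extents[1] < 1e-6:
        raise ValueError("markers are (nearly) collinear; rotation is not recoverable")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    if about is None:
        about = c_ref
    about = np.asarray(about, float).reshape(3)
    t = c_def - (rot @ (c_ref - about) + about)
    transform = RigidTransform(rot, t, about)
    residual = float(np.sqrt(np.mean(np.sum((transform.apply(ref) - deformed) ** 2, axis=1))))
    return transform, residual
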