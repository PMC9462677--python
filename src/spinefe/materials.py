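"""Density-to-elasticity material mapping for QCT-based bone models.

The chain is the standard calibrated-QCT route: Hounsfield units are
converted to QCT-equivalent mineral density through the scanner/phantom
calibration line, QCT density to ash density through a wet-ashing
regression, ash density to apparent density by a fixed ash fraction, and
apparent density to an isotropic elastic modulus through a power law.
All densities are in g/cm^3 and moduli in MPa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

log = logging.getLogger(__name__)

__all__ = [
    "MaterialLaw",
    "DensityGrid",
    "hu_to_rho_qct",
    "rho_qct_to_modulus",
    "map_materials",
    "material_report",
]


@dataclass(frozen=True)
class MaterialLaw:
    """Constants of the HU -> density -> modulus chain.

    Defaults are the European-Spine-Phantom calibration line, the ash-density
    regression for vertebral bone, a 0.6 ash/apparent ratio and the
    vertebral-trabecular modulus power law (E in MPa, densities in g/cm^3).
    """

    cal_intercept: float = -0.016404   # g/cm^3 at HU = 0
    cal_slope: float = 0.00085164      # g/cm^3 per HU
    ash_intercept: float = 0.079       # g/cm^3
    ash_slope: float = 0.877
    app_ratio: float = 0.6             # rho_ash / rho_app
    mod_coeff: float = 4730.0          # MPa
    mod_exp: float = 1.56
    nu_bone: float = 0.3
    e_floor: float = 0.01              # MPa; keeps stiffness positive definite

    def __post_init__(self) -> None:
        if self.cal_slope <= 0 or self.ash_slope <= 0:
            raise ValueError("calibration and ash slopes must be positive")
        if not (0.0 < self.app_ratio <= 1.0):
            raise ValueError("app_ratio must lie in (0, 1]")
        if self.mod_coeff <= 0 or self.mod_exp <= 0:
            raise ValueError("modulus power law must have positive constants")
        if not (0.0 <= self.nu_bone < 0.5):
            raise ValueError("nu_bone must lie in [0, 0.5)")
        if self.e_floor <= 0:
            raise ValueError("e_floor must be positive")


@dataclass
class DensityGrid:
    """Calibrated scalar field on a regular voxel lattice.

    ``values`` has shape ``dims`` (nx, ny, nz); voxel centres sit at
    ``origin + index * spacing``.  ``value_kind`` is ``"HU"`` or
    ``"rho_qct"`` and decides whether the calibration line is applied
    before the density chain.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    value_kind: str = "HU"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if self.value_kind not in ("HU", "rho_qct"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-centre bounding box (lo, hi)."""
        hi = self.origin + self.spacing * (np.array(self.dims) - 1)
        return self.origin.copy(), hi

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator over voxel centres (clamped at the edges)."""
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.dims[k])
            for k in range(3)
        ]
        return RegularGridInterpolator(
            axes, self.values, method="linear", bounds_error=False, fill_value=None
        )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly sample the field at ``points`` (clamped to the box)."""
        pts = np.asarray(points, dtype=float)
        lo, hi = self.bounds
        clamped = np.clip(pts, lo, hi)
        return self.interpolator()(clamped)


def hu_to_rho_qct(hu, law: MaterialLaw = MaterialLaw()):
    """Calibration line: HU -> QCT-equivalent density (g/cm^3).

    Affine map ``cal_intercept + cal_slope * HU`` applied element-wise.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU input contains non-finite values")
    out = law.cal_intercept + law.cal_slope * hu
    return out if out.ndim else float(out)


def rho_qct_to_modulus(rho_qct, law: MaterialLaw = MaterialLaw()):
    """QCT density -> (ash density, apparent density, modulus).

    rho_ash = ash_intercept + ash_slope * rho_qct, rho_app = rho_ash /
    app_ratio, E = mod_coeff * rho_app ** mod_exp clamped below at
    ``law.e_floor``.  Non-positive apparent densities (air, background)
    are clamped to the floor with a warning.
    """
    rho_qct = np.asarray(rho_qct, dtype=float)
    if not np.all(np.isfinite(rho_qct)):
        raise ValueError("rho_qct input contains non-finite values")
    rho_ash = law.ash_intercept + law.ash_slope * rho_qct
    rho_app = rho_ash / law.app_ratio
    nonphys = rho_app <= 0
    if np.any(nonphys):
        warnings.warn(
            "non-physical (<= 0) apparent density clamped to the modulus floor",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        e = np.where(
            nonphys,
            law.e_floor,
            law.mod_coeff * np.abs(rho_app) ** law.mod_exp,
        )
    e = np.maximum(e, law.e_floor)
    if rho_qct.ndim == 0:
        return float(rho_ash), float(rho_app), float(e)
    return rho_ash, rho_app, e


def hu_to_modulus(hu, law: MaterialLaw = MaterialLaw()):
    """Fused HU -> E evaluation (exact composition of the two steps)."""
    return rho_qct_to_modulus(hu_to_rho_qct(hu, law), law)[2]


def _element_sample_points(nodes: np.ndarray, tets: np.ndarray, n_samples: int) -> np.ndarray:
    """Fixed interior sample points for each tetrahedron.

    ``n_samples <= 4`` uses the symmetric 4-point second-order rule;
    otherwise the tet is split into its 8 equal-volume sub-tets (4 corner
    tets + 4 from the inner octahedron) and their centroids are used.
    Either set is deterministic and independent of node ordering up to
    permutation, and all weights are equal, so the element average is a
    plain mean over samples.
    """
    v = nodes[tets[:, :4]]  # (E, 4, 3) corner vertices
    if n_samples <= 4:
        a, b = 0.5854101966249685, 0.1381966011250105
        bary = np.array(
            [[a, b, b, b], [b, a, b, b], [b, b, a, b], [b, b, b, a]][:max(1, n_samples)]
        )
        if n_samples == 1:
            bary = np.array([[0.25, 0.25, 0.25, 0.25]])
        return np.einsum("sk,ekd->esd", bary, v)
    # 8 equal-volume sub-tets: centroids expressed in corner barycentrics.
    m = {  # edge midpoints in barycentric coordinates
        (i, j): tuple((np.eye(4)[i] + np.eye(4)[j]) / 2) for i in range(4) for j in range(4)
    }
    e4 = [tuple(row) for row in np.eye(4)]
    subtets = []
    for i in range(4):
        others = [j for j in range(4) if j != i]
        subtets.append([e4[i]] + [m[(i, j)] for j in others])
    # inner octahedron split through the (0,1)-(2,3) midpoint diagonal
    d0, d1 = m[(0, 1)], m[(2, 3)]
    ring = [m[(0, 2)], m[(1, 2)], m[(1, 3)], m[(0, 3)]]
    for k in range(4):
        subtets.append([d0, d1, ring[k], ring[(k + 1) % 4]])
    bary = np.array([np.mean(st, axis=0) for st in subtets])  # (8, 4)
    return np.einsum("sk,ekd->esd", bary, v)


def map_materials(
    mesh,
    grid: DensityGrid,
    law: MaterialLaw = MaterialLaw(),
    samples_per_element: int = 8,
):
    """Assign per-element (E, nu) on the bone elements of ``mesh``.

    Each bone element's modulus is the average of the point-wise moduli at
    ``samples_per_element`` fixed interior points (modulus averaging: the
    HU value is converted to E at every sample *before* averaging).
    Elements whose bounding box lies entirely outside the grid get the
    modulus floor.  Disc elements are left untouched; their homogeneous
    material is set by the disc calibration.
    """
    if samples_per_element < 1:
        raise ValueError("samples_per_element must be >= 1")
    if mesh.n_elements == 0:
        raise ValueError("mesh has no elements")
    pts = _element_sample_points(mesh.nodes, mesh.elements, samples_per_element)
    ne, ns, _ = pts.shape
    vals = grid.sample(pts.reshape(-1, 3)).reshape(ne, ns)
    if grid.value_kind == "HU":
        rho_qct = hu_to_rho_qct(vals, law)
    else:
        rho_qct = vals
    _, _, e_samples = rho_qct_to_modulus(rho_qct, law)
    e_elem = e_samples.mean(axis=1)

    lo, hi = grid.bounds
    emin = pts.min(axis=1)
    emax = pts.max(axis=1)
    outside = np.any(emax < lo, axis=1) | np.any(emin > hi, axis=1)
    e_elem[outside] = law.e_floor

    disc_mask = mesh.disc_mask()
    if mesh.E is None:
        mesh.E = np.full(mesh.n_elements, law.e_floor)
        mesh.nu = np.full(mesh.n_elements, law.nu_bone)
    keep = ~disc_mask
    mesh.E[keep] = e_elem[keep]
    mesh.nu[keep] = law.nu_bone
    log.info(
        "mapped materials on %d bone elements (%d skipped as disc, %d outside grid)",
        int(keep.sum()), int(disc_mask.sum()), int(outside.sum()),
    )
    mesh._rho_qct_mean = rho_qct.mean(axis=1)  # cached for reports
    return mesh


def material_report(mesh, law: MaterialLaw = MaterialLaw()):
    """Per-element density/modulus table (element id, densities, E)."""
    import pandas as pd

    rho_qct = getattr(mesh, "_rho_qct_mean", None)
    if rho_qct is None:
        raise ValueError("run map_materials before requesting a report")
    rho_ash, rho_app, _ = rho_qct_to_modulus(rho_qct, law)
    return pd.DataFrame(
        {
            "element": np.arange(mesh.n_elements),
            "rho_qct": rho_qct,
            "rho_ash": rho_ash,
            "rho_app": rho_app,
            "E": mesh.E,
        }
    )
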