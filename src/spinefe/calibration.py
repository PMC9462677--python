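"""Disc-modulus calibration against a target axial force.

The intervertebral discs are modelled as a single homogeneous isotropic
material (Poisson's ratio 0.1 by default) whose modulus is unknown a
priori: no CT-derived estimate exists for disc tissue.  The modulus is
therefore calibrated so that, under the prescribed pot motion, the axial
reaction at the fixed base matches the experimentally measured force.

Because the global stiffness is affine in the disc modulus
(K(E) = K_bone + E * K_disc_unit), the two blocks are assembled once and
each calibration iteration only re-solves the linear system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fe import BoundaryConditions, FESolution, apply_bcs_and_solve, assemble
from .mesh import TetMesh

__all__ = ["DiscModel", "CalibrationResult", "calibrate_disc_modulus"]


@dataclass(frozen=True)
class DiscModel:
    """Homogeneous isotropic disc material with an unknown modulus."""

    nu_disc: float = 0.1
    bracket: tuple[float, float] = (0.1, 100.0)   # MPa search interval

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not (0 < lo < hi):
            raise ValueError("bracket must be positive and ordered")
        if not (0 <= self.nu_disc < 0.5):
            raise ValueError("nu_disc must lie in [0, 0.5)")


@dataclass
class CalibrationResult:
    e_disc: float                # MPa
    achieved_force: float        # N (axial magnitude)
    relative_difference: float   # |achieved - target| / target
    iterations: int
    solution: FESolution
    log: pd.DataFrame            # iteration, E_disc, axial force, rel. difference


def _split_stiffness(mesh: TetMesh, disc: DiscModel):
    """K_bone (disc modulus zeroed) and K_disc at unit modulus."""
    disc_mask = mesh.disc_mask()
    if not disc_mask.any():
        raise ValueError("mesh has no disc element sets (disc_*)")
    if mesh.E is None:
        raise ValueError("bone materials not assigned; run map_materials first")
    e0, nu0 = mesh.E.copy(), mesh.nu.copy()
    try:
        mesh.E = np.where(disc_mask, 0.0, e0)
        mesh.nu = np.where(disc_mask, disc.nu_disc, nu0)
        k_bone = assemble(mesh)
        mesh.E = np.where(disc_mask, 1.0, 0.0)
        k_disc = assemble(mesh)
    finally:
        mesh.E, mesh.nu = e0, nu0
    return k_bone, k_disc, disc_mask


def calibrate_disc_modulus(
    mesh: TetMesh,
    bcs: BoundaryConditions,
    target_force: float | None = None,
    rel_tol: float = 1e-3,
    disc: DiscModel = DiscModel(),
    max_iter: int = 50,
) -> CalibrationResult:
    """Find the disc modulus whose axial reaction matches ``target_force``.

    Root finding is bisection with secant acceleration on the monotone
    map E_disc -> |axial reaction|; terminates when the relative force
    mismatch drops below ``rel_tol`` (default 0.1%).  The endpoint solves
    double as the bracketing and monotonicity check.  On return the disc
    elements of ``mesh`` carry the calibrated modulus.
    """
    if target_force is None:
        target_force = bcs.target_axial_force
    if target_force is None or target_force <= 0:
        raise ValueError("a positive target axial force is required")
    k_bone, k_disc, disc_mask = _split_stiffness(mesh, disc)

    def solve_at(e: float) -> tuple[float, FESolution]:
        mesh.E = np.where(disc_mask, e, mesh.E)
        mesh.nu = np.where(disc_mask, disc.nu_disc, mesh.nu)
        sol = apply_bcs_and_solve(mesh, bcs, k=(k_bone + e * k_disc).tocsr())
        return abs(sol.axial_resultant), sol

    lo, hi = disc.bracket
    f_lo, _ = solve_at(lo)
    f_hi, sol_hi = solve_at(hi)
    rows = [(0, lo, f_lo, abs(f_lo - target_force) / target_force),
            (0, hi, f_hi, abs(f_hi - target_force) / target_force)]
    if f_lo >= f_hi:
        raise ValueError(
            f"axial reaction not increasing over the bracket: F({lo})={f_lo:.3g} N, "
            f"F({hi})={f_hi:.3g} N"
        )
    if not (f_lo <= target_force <= f_hi):
        raise ValueError(
            f"target {target_force:.3g} N outside attainable range "
            f"[{f_lo:.3g}, {f_hi:.3g}] N for bracket [{lo}, {hi}] MPa"
        )

    a, fa, b, fb = lo, f_lo, hi, f_hi
    e, f, sol = b, fb, sol_hi
    for it in range(1, max_iter + 1):
        rel = abs(f - target_force) / target_force
        if rel <= rel_tol:
            break
        # secant proposal, midpoint fallback when it leaves the bracket
        if fb != fa:
            e = a + (target_force - fa) * (b - a) / (fb - fa)
        if not (a < e < b):
            e = 0.5 * (a + b)
        f, sol = solve_at(e)
        rel = abs(f - target_force) / target_force
        rows.append((it, e, f, rel))
        if f < target_force:
            a, fa = e, f
        else:
            b, fb = e, f
    else:
        it = max_iter
    rel = abs(f - target_force) / target_force
    log = pd.DataFrame(rows, columns=["iteration", "E_disc", "axial_force", "rel_difference"])
    return CalibrationResult(float(e), float(f), float(rel), it, sol, log)
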