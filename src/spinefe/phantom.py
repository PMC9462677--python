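"""Synthetic spine-segment specimens for end-to-end pipeline testing.

No public dataset pairs a calibrated QCT scan of a spine segment with
full-field surface displacement measurements, so every stage of the
pipeline is exercised on a generated specimen instead: an idealized
L1-L4 stack (two full vertebral bodies, two embedded half bodies, three
discs) built from coaxial cylinders.  The density field mimics what a
vertebra looks like on calibrated CT — a denser peripheral shell around
a low-density (marrow-like) core — with a lytic lesion eating into the
anterior shell of L2 and an osteoporotic L3.  The loading replicates a
compression-flexion test driven through a pot whose rigid motion is
tracked by a four-marker cluster, and the measured cloud is emulated by
sampling the FE surface displacement at ~2 mm spacing with the
systematic and random error levels of a stereo-DIC system.

The geometry is idealized on purpose: the pipeline contract (mapping,
constraints, calibration, registration, metrics), not vertebral anatomy,
is what the phantom makes testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fe import BoundaryConditions, FESolution
from .kinematics import MarkerCluster, RigidTransform
from .materials import DensityGrid, MaterialLaw
from .mesh import TetMesh, cylinder_stack_mesh
from .registration import SurfaceField, apply_transform

__all__ = ["PhantomSpec", "make_phantom", "synth_dic_cloud", "synth_marker_frames",
           "roi_surface_nodes", "roi_mean_axial_strain", "convergence_study"]


def _rot(axis: int, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = m[j, j] = c
    m[i, j], m[j, i] = -s, s
    return m


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, densities, loading and measurement noise of the phantom.

    Densities are QCT-equivalent vBMD in g/cm^3 (the reported clinical
    values: lesion 0.105, osteoporotic body 0.076); the voxel grid itself
    is synthesized in HU by inverting the calibration line, so the
    phantom is consistent with the material-mapping chain.  Lengths mm,
    load N.
    """

    radius: float = 6.0                 # vertebral body radius
    shell_wall: float = 0.9             # dense peripheral shell thickness
    full_height: float = 14.0           # L2, L3
    half_height: float = 7.0            # embedded halves of L1 and L4
    disc_height: float = 4.0
    background_vbmd: float = 0.520      # g/cm^3, healthy shell (L1, L2, L4)
    osteoporotic_vbmd: float = 0.076    # g/cm^3, L3 shell
    lesion_vbmd: float = 0.105          # g/cm^3, lytic region in L2
    lesion_semiaxes: tuple = (2.5, 2.5, 3.5)
    core_hu: float = -50.0              # fatty-marrow core
    endplate_height: float = 1.5        # cartilage endplate between disc and bone
    endplate_hu: float = -58.0          # maps to E ~ 25 MPa, grading the contrast
    air_hu: float = -1000.0
    voxel_spacing: tuple = (0.24, 0.24, 1.0)
    grid_margin: float = 1.5            # mm of air around the specimen
    mesh_edge: float = 2.0
    order: int = 10                     # tet10 by default
    anterior_offset_fraction: float = 0.10   # of the disc AP dimension
    target_load: float = 60.0           # N
    compression: float = 3.39           # mm, pilot axial travel (tuned to ~60 N)
    flexion_deg: float = 8.0            # forward bend of the top pot
    lateral_bending_deg: float = 4.0    # parasitic bend (free ball-joint mounting)
    axial_rotation_deg: float = 7.0     # parasitic twist
    lateral_shift: tuple = (1.9, 3.8)   # mm, pot lean consistent with the bend
    marker_standoff: float = 5.0        # mm above the top surface
    dic_noise_random: float = 0.025     # mm (1 sd per component)
    dic_noise_systematic: float = 0.010 # mm (constant offset magnitude)
    dic_spacing: float = 2.0            # mm, cloud point spacing
    roi_margin: float = 2.0             # mm kept clear of the endplates, as in DIC
    refine: int = 0                     # nested uniform refinements of the base mesh
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("radius", "shell_wall", "full_height", "half_height",
                     "disc_height", "mesh_edge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dic_noise_random < 0 or self.dic_noise_systematic < 0:
            raise ValueError("noise levels must be non-negative")
        if not (0.0 <= self.anterior_offset_fraction <= 0.5):
            raise ValueError("anterior_offset_fraction must lie in [0, 0.5]")

    @property
    def total_height(self) -> float:
        return (2 * self.half_height + 2 * self.full_height
                + 3 * self.disc_height + 6 * self.endplate_height)

    @property
    def layers(self) -> list[tuple[str, float]]:
        """Bottom-to-top element-set layout (L4 caudal, L1 cranial).

        Each disc is sandwiched between cartilage-endplate layers, which
        grade the three-orders-of-magnitude disc/cortex stiffness jump
        the way the real joint does.
        """
        ep = self.endplate_height / 2.0
        dh = self.disc_height / 2.0

        # soft layers listed as half-height pairs: the mesher then resolves
        # them with at least two element layers through the thickness, where
        # the deformation (and hence discretization error) concentrates
        def disc(k):
            return [(f"plate_{2*k-1}", ep)] * 2 + [(f"disc_{k}", dh)] * 2 \
                + [(f"plate_{2*k}", ep)] * 2

        return ([("bone_L4", self.half_height)] + disc(3)
                + [("bone_L3", self.full_height)] + disc(2)
                + [("bone_L2", self.full_height)] + disc(1)
                + [("bone_L1", self.half_height)])

    @property
    def anterior_offset(self) -> float:
        """Load-line offset: fraction of the disc AP dimension d = 2r."""
        return self.anterior_offset_fraction * 2.0 * self.radius

    def vertebra_z_range(self, name: str) -> tuple[float, float]:
        z = 0.0
        for lname, h in self.layers:
            if lname == name:
                return z, z + h
            z += h
        raise KeyError(name)

    def pilot_motion(self, compression: float | None = None,
                     flexion_deg: float | None = None,
                     pilot: np.ndarray | None = None) -> RigidTransform:
        """Compression-flexion rigid pot motion about the pilot point.

        Dominantly axial compression plus a forward bend, with the small
        lateral bend, twist and in-plane shift a free ball-joint mounting
        leaves in the real pot motion; all rotations are applied as full
        rotation matrices (not linearized).
        """
        if compression is None:
            compression = self.compression
        if flexion_deg is None:
            flexion_deg = self.flexion_deg
        if pilot is None:
            pilot = self.pilot_point()
        rot = (_rot(0, np.deg2rad(flexion_deg))
               @ _rot(1, np.deg2rad(self.lateral_bending_deg))
               @ _rot(2, np.deg2rad(self.axial_rotation_deg)))
        t = np.array([self.lateral_shift[0], self.lateral_shift[1], -compression])
        return RigidTransform(rot, t, about=np.asarray(pilot, float))

    def pilot_point(self) -> np.ndarray:
        """Marker-cluster centroid: above the top surface, offset anteriorly."""
        return np.array([0.0, self.anterior_offset,
                         self.total_height + self.marker_standoff])


def _density_grid(spec: PhantomSpec, law: MaterialLaw) -> DensityGrid:
    """HU voxel grid: air outside the cylinder, shell/core/lesion inside."""
    def hu_of(vbmd):  # invert the calibration line
        return (vbmd - law.cal_intercept) / law.cal_slope

    sp = np.asarray(spec.voxel_spacing, float)
    r, m = spec.radius, spec.grid_margin
    lo = np.array([-(r + m), -(r + m), -m])
    hi = np.array([r + m, r + m, spec.total_height + m])
    dims = np.ceil((hi - lo) / sp).astype(int) + 1
    ax = [lo[k] + sp[k] * np.arange(dims[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rad = np.sqrt(X ** 2 + Y ** 2)

    values = np.full(dims, spec.air_hu)
    inside = rad <= r
    values[inside] = spec.core_hu
    shell = inside & (rad >= r - spec.shell_wall)
    z0 = 0.0
    for name, h in spec.layers:
        zone = inside & (Z >= z0) & (Z < z0 + h)
        if name.startswith("bone"):
            vbmd = spec.osteoporotic_vbmd if name == "bone_L3" else spec.background_vbmd
            values[zone & shell] = hu_of(vbmd)
        elif name.startswith("plate"):
            values[zone] = spec.endplate_hu
        else:
            values[zone] = 0.0  # water-equivalent disc space (unused by mapping)
        z0 += h
    # lytic lesion: ellipsoid breaching the anterior shell of L2
    zl = np.mean(spec.vertebra_z_range("bone_L2"))
    cx, cy, cz = 0.0, r - spec.shell_wall / 2.0 - spec.lesion_semiaxes[1] / 2.0, zl
    a, b, c = spec.lesion_semiaxes
    les = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
    values[les & inside] = hu_of(spec.lesion_vbmd)
    return DensityGrid(origin=lo, spacing=sp, values=values, value_kind="HU")


def lesion_mask_elements(mesh: TetMesh, spec: PhantomSpec) -> np.ndarray:
    """Elements whose centroid lies inside the L2 lesion ellipsoid."""
    cen = mesh.nodes[mesh.elements[:, :4]].mean(axis=1)
    r = spec.radius
    zl = np.mean(spec.vertebra_z_range("bone_L2"))
    cy = r - spec.shell_wall / 2.0 - spec.lesion_semiaxes[1] / 2.0
    a, b, c = spec.lesion_semiaxes
    return ((cen[:, 0] / a) ** 2 + ((cen[:, 1] - cy) / b) ** 2
            + ((cen[:, 2] - zl) / c) ** 2) <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec(), law: MaterialLaw = MaterialLaw()):
    """Build the full synthetic specimen.

    Returns ``(grid, mesh, bcs, (top_markers, bottom_markers))``: the HU
    voxel grid, the labelled tet mesh (without materials — run
    ``map_materials``), boundary conditions with the compression-flexion
    pilot motion and the 60 N force target, and the two marker clusters.
    Deterministic: the phantom geometry involves no randomness; only the
    measurement emulation (clouds, marker noise) consumes the seed.
    """
    if spec.disc_height <= 0:
        raise ValueError("disc height must be positive")
    mesh = cylinder_stack_mesh(spec.radius, spec.layers, edge=spec.mesh_edge,
                               order=4)
    for _ in range(spec.refine):   # nested levels share the exact domain
        mesh = mesh.refine()
    if spec.order == 10:
        mesh = mesh.to_tet10()
    grid = _density_grid(spec, law)

    ztol = 1e-9 + 1e-6 * spec.total_height
    fixed = np.where(np.abs(mesh.nodes[:, 2]) < ztol)[0]
    tied = np.where(np.abs(mesh.nodes[:, 2] - spec.total_height) < ztol)[0]

    top = synth_marker_frames(spec.pilot_motion(), spec, which="top")
    bottom = synth_marker_frames(RigidTransform.identity(), spec, which="bottom")
    pilot = top.reference.mean(axis=0)

    bcs = BoundaryConditions(
        fixed_nodes=fixed, tied_nodes=tied, pilot=pilot,
        pilot_motion=spec.pilot_motion(pilot=pilot),
        target_axial_force=spec.target_load,
        axial_dir=np.array([0.0, 0.0, 1.0]),
    )
    return grid, mesh, bcs, (top, bottom)


_MARKER_LAYOUT = np.array([
    [5.0, 0.0, -1.0], [-5.0, 0.0, -1.0], [0.0, 5.0, 1.0], [0.0, -5.0, 1.0],
])  # 4 non-coplanar markers, centroid at the origin


def synth_marker_frames(motion: RigidTransform, spec: PhantomSpec = PhantomSpec(),
                        which: str = "top", noise: float = 0.0,
                        rng: np.random.Generator | None = None) -> MarkerCluster:
    """Marker cluster on a pot: reference layout + rigidly moved frame.

    The cluster is 4 non-coplanar markers around the pot centre (top pot:
    above the cranial surface at the anterior load offset; bottom pot:
    below the caudal surface).  Optional isotropic Gaussian noise of
    standard deviation ``noise`` mm is added to the deformed frame.
    """
    if which == "top":
        center = spec.pilot_point()
    else:
        center = np.array([0.0, 0.0, -spec.marker_standoff])
    ref = _MARKER_LAYOUT + center
    deformed = motion.apply(ref)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        deformed = deformed + rng.normal(0.0, noise, deformed.shape)
    return MarkerCluster(ids=np.arange(ref.shape[0]), reference=ref, deformed=deformed)


def roi_surface_nodes(mesh: TetMesh, spec: PhantomSpec, vertebra: str = "bone_L3",
                      anterior_only: bool = True) -> np.ndarray:
    """Corner surface nodes of the antero-lateral RoI of one vertebra.

    Mirrors the optically visible correlation area: the lateral surface
    of the vertebral body, restricted to the anterior half (y >= 0) where
    the cameras look, excluding nodes shared with the adjacent discs.
    """
    surf = np.intersect1d(mesh.surface_nodes(), mesh.nodes_in_set(vertebra))
    xyz = mesh.nodes[surf]
    zlo, zhi = spec.vertebra_z_range(vertebra)
    eps = max(spec.roi_margin, 1e-6)
    sel = (xyz[:, 2] > zlo + eps) & (xyz[:, 2] < zhi - eps)
    sel &= np.sqrt(xyz[:, 0] ** 2 + xyz[:, 1] ** 2) >= spec.radius - 0.3
    if anterior_only:
        sel &= xyz[:, 1] >= -1e-9
    return surf[sel]


def roi_mean_axial_strain(solution: FESolution, spec: PhantomSpec,
                          vertebra: str = "bone_L3") -> float:
    """Mean axial (z) strain of the anterior surface elements of a vertebra."""
    mesh = solution.mesh
    ids = np.asarray(mesh.element_sets[vertebra])
    cen = mesh.nodes[mesh.elements[ids, :4]].mean(axis=1)
    sel = (np.sqrt(cen[:, 0] ** 2 + cen[:, 1] ** 2) >= spec.radius - spec.shell_wall)
    sel &= cen[:, 1] >= 0
    return float(solution.strain[ids[sel], 2].mean())


def convergence_study(spec: PhantomSpec | None = None, e_disc: float = 1.92,
                      levels: int = 2, law: MaterialLaw = MaterialLaw()) -> dict:
    """Nested mesh-refinement study of the maximum RoI displacement.

    Each level uniformly refines the same base mesh (the domain is bit-
    identical across levels), and the displacement magnitude is compared
    at the base level's RoI nodes, which every nested level contains at
    the same indices — so the numbers measure discretization error only,
    not re-sampling of the evaluation points.  Returns the per-level
    ``max_u`` (mm) and the relative changes between consecutive levels.

    The default base (2.5 mm edge) puts the finest level at the limit a
    direct solve handles comfortably in memory.
    """
    from .calibration import DiscModel
    from .fe import apply_bcs_and_solve
    from .materials import map_materials

    if spec is None:
        spec = PhantomSpec(mesh_edge=2.5)
    base_roi = None
    max_u, n_elements = [], []
    for lev in range(levels):
        s = replace(spec, refine=lev)
        grid, mesh, bcs, _ = make_phantom(s, law)
        map_materials(mesh, grid, law)
        dm = mesh.disc_mask()
        mesh.E[dm] = e_disc
        mesh.nu[dm] = DiscModel().nu_disc
        sol = apply_bcs_and_solve(mesh, bcs)
        if base_roi is None:
            base_roi = np.concatenate(
                [roi_surface_nodes(mesh, s, v) for v in ("bone_L2", "bone_L3")])
            base_xyz = mesh.nodes[base_roi]
        assert np.allclose(mesh.nodes[base_roi], base_xyz)  # nested node identity
        max_u.append(float(np.linalg.norm(sol.u[base_roi], axis=1).max()))
        n_elements.append(mesh.n_elements)
    changes = [abs(max_u[i + 1] - max_u[i]) / max_u[i + 1]
               for i in range(len(max_u) - 1)]
    return {"max_u": max_u, "n_elements": n_elements, "rel_changes": changes}


def synth_dic_cloud(solution: FESolution, roi_nodes: np.ndarray,
                    spec: PhantomSpec = PhantomSpec(),
                    rng: np.random.Generator | None = None,
                    noise: bool = True,
                    misregistration: RigidTransform | None = None,
                    roi_label: str = "custom") -> SurfaceField:
    """Emulated DIC measurement of the solved surface displacement field.

    Cloud points sit at the RoI surface nodes (~``dic_spacing`` apart for
    the default 2 mm mesh, matching the optical spatial resolution); each
    displacement is the FE value plus a constant systematic offset (fixed
    random direction, magnitude ``dic_noise_systematic``) and iid
    zero-mean Gaussian noise (``dic_noise_random`` per component).  A
    known mis-registration transform can be pre-applied to exercise the
    registration stage.
    """
    roi_nodes = np.asarray(roi_nodes, dtype=np.int64)
    if roi_nodes.size == 0:
        raise ValueError("RoI is empty")
    pts = solution.mesh.nodes[roi_nodes].copy()
    disp = solution.u[roi_nodes].copy()
    if noise and (spec.dic_noise_random > 0 or spec.dic_noise_systematic > 0):
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp = disp + spec.dic_noise_systematic * direction
        disp = disp + rng.normal(0.0, spec.dic_noise_random, disp.shape)
    fld = SurfaceField(points=pts, displacements=disp, roi_label=roi_label)
    if misregistration is not None:
        fld = apply_transform(fld, misregistration)
    return fld
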