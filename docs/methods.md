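# Methods

## Scope and model

`spinefe` models a multi-vertebra lumbar segment under displacement-
controlled compression-flexion and validates the predicted surface
displacement field against full-field optical measurements. The
mechanical model is deliberately the simplest one the validation
literature supports: small-strain linear elasticity, heterogeneous
isotropic bone mapped from calibrated CT, homogeneous isotropic discs,
no contact, no posterior elements, no failure. Units are mm, N, MPa
throughout (a consistent system at the magnitudes involved).

## Density-to-modulus mapping

The chain is HU -> rho_QCT (scanner calibration line) -> rho_ash (ash
regression) -> rho_app = rho_ash / 0.6 -> E = 4730 rho_app^1.56 MPa,
nu = 0.3. Constants live in `MaterialLaw` and are configurable; the
defaults are the European-Spine-Phantom calibration and the vertebral
power law. Two numerical choices matter:

- **Modulus averaging.** The conversion is applied at fixed sample
  points inside each element *before* averaging (8 points by default:
  centroids of the eight equal-volume sub-tets; <= 4 requests the
  symmetric second-order point set). Averaging E rather than HU is the
  strategy of the established mapping tools; with 8 interior points a
  2 mm element sees sub-voxel structure without smoothing across it.
- **Floor clamp.** Non-physical densities (air, marrow below the ash
  intercept) clamp to E = 0.01 MPa with a warning, keeping the global
  stiffness positive definite while contributing negligible load path.
  Elements entirely outside the grid get the floor.

Grid sampling is trilinear between voxel centres, clamped at the box
boundary; deterministic and independent of element order.

## Elasticity core

Isoparametric tet4/tet10 with exact (4-point) Gauss integration for the
quadratic element; assembly is vectorized over elements. The verifiable
contracts are the patch test (affine fields reproduced to 1e-9
relative), the nu = 0 cube compression against the rod formula E A d/L
(1e-8 relative) and a global equilibrium residual below 1e-8 on every
solve; all three are enforced in the test suite.

Boundary conditions replicate the experiment: the caudal surface fixed,
the cranial surface rigidly tied to a pilot node at the marker-cluster
centroid, with the pilot's finite rotation applied as a full rotation
matrix (a ~5 degree pot rotation is small but not negligible; the
linearized form would leave second-order residues in the tied-surface
kinematics). Because every constrained dof is fully prescribed, the
constrained system is solved by reduction to the free dofs and a sparse
direct factorization; this is algebraically the Lagrange-multiplier
formulation of the same constraints, and the reaction at a constrained
dof — identical to the multiplier — is recovered as the stiffness
residual there. The axial resultant is the fixed-set reaction component
along a configurable axis (default the cranio-caudal z).

The embedding pots are not meshed: the tie acts directly on the
vertebral end surface, consistent with treating pot + PMMA as a single
rigid body.

## Rigid kinematics and registration

Pot motion comes from >= 3 non-collinear markers by the closed-form SVD
(Kabsch) solution with the determinant guard, reported about an explicit
reference point (the pilot SP) to avoid the about-the-origin ambiguity
of rigid transforms. With isotropic marker noise sigma the translation
error scales as sigma/sqrt(M); the suite checks this at sigma = 10 um.

Cloud-to-mesh registration is PCA-initializable ICP with two
correspondence phases: point-to-nearest-surface-point sweeps first
(exact point-triangle projection; candidate faces from a KD-tree over
face centroids), then point-to-nearest-surface-node refinement. The
second phase exists because a vertebral body is feature-poor and locally
near-cylindrical: point-to-surface correspondences leave tangential
sliding essentially unconstrained and the iteration stalls at a few
micrometres, while node correspondences pin it; when the cloud samples
the surface nodes themselves the node phase converges to machine
precision. Registration error is reported against the nearest surface
*node* (the convention of the reported RMSE) and against the nearest
surface point, both. A genuine limitation remains: rotations about the
local surface axis of symmetry beyond a few degrees are weakly
observable from a single patch — real studies face the same problem and
solve it with features away from the patch.

Clouds are triangulated by best-fit-plane Delaunay with an edge cutoff
of 3x the median point spacing (trims convex-hull bridges); losing the
majority of triangles to the cutoff, or > 5% folded normals, raises a
geometry error suggesting per-region splitting. Applying a transform to
a measured field moves the points fully but only *rotates* the
displacement vectors — displacements are differences of positions and
carry no translation.

## Disc calibration

E_disc is found by bisection with secant acceleration on the monotone
map E_disc -> |axial reaction|, bracket [0.1, 100] MPa, stop when the
force mismatch is <= 0.1% (the study's acceptance rule), max 50
iterations. The endpoint solves double as the bracketing and
monotonicity check. Since K(E_disc) = K_bone + E_disc * K_disc_unit, the
two blocks are assembled once and each iteration only re-solves; this
is exact, not an approximation.

## Validation statistics

Measured vectors are averaged (unweighted) over a sphere of radius R
centred on each model RoI node; R defaults to the registration RMSE
(floored at 0.1 mm in the pipeline — a perfectly registered synthetic
cloud would otherwise shrink the sphere to nothing). Cook's-distance
filtering (D_i > 4x mean, single pass, per component per region, on the
predicted-vs-measured simple regression) precedes the metrics;
numerically perfect fits skip the filter, since their D_i are rounding
noise. Reported per region and component: R^2, slope, intercept, RMSE
of (measured - predicted), %RMSE normalized by the largest measured
component magnitude in the region, average percentage error (points with
measured component < 1 um excluded from the average — the ratio blows
up — and counted separately), maximum absolute error, and the pointwise
Error/Error%/Diff fields. Bland-Altman output supports both the signed
per-component difference and the resultant-magnitude convention.

## The synthetic specimen

No public dataset pairs calibrated QCT of a spine segment with DIC
surface fields, so the pipeline ships a generator whose outputs have
the statistical structure the method assumes. Geometry is an idealized
stack of coaxial cylinders (L1 half, discs with cartilage endplates, L2,
L3, L4 half); the density field gives each vertebra a dense shell
(0.520 g/cm^3 vBMD; the osteoporotic L3 0.076) around a marrow-like
core, a lytic lesion ellipsoid (0.105 g/cm^3) breaching the anterior
shell of L2, endplates at about 25 MPa, and air outside — written as HU
by inverting the calibration line so the phantom is consistent with the
mapping chain. Default measurement emulation: cloud points at the RoI
surface nodes (~2 mm spacing, the optical spatial resolution), 25 um
random and 10 um systematic displacement error, optional known
mis-registration; markers are 4 non-coplanar points per pot.

The loading is a prescribed pot motion of 3.39 mm compression with 8
degree flexion, 4 degree lateral bend, 7 degree axial twist and a
(1.9, 3.8) mm in-plane lean consistent with distributed bending. These
values were fixed once, by design, so that the phantom reproduces the
study conditions: ~60 N axial reaction at the reference disc modulus
(1.92 MPa), a mean anterior-surface axial strain on the lower vertebra
inside the physiological -2500..-3500 microstrain window at the target
load, and enough spatial variation of *every* displacement component
within a region (>= ~100 um sd) that the per-component regressions are
signal- rather than noise-dominated at DIC noise levels. A pure
compression motion fails that last condition structurally: within one
nearly rigid vertebra the transverse components are then spatially
constant and no measurement system could regress them. The rotational
components stand in for the lean and twist a ball-joint mounting leaves
in a real test.

What the phantom does *not* emulate: real vertebral geometry (posterior
elements, endplate curvature), anisotropy, the speckle-correlation
process itself, and realistic disc strain levels — at 60 N over a
~110 mm^2 disc the linear model sees ~25% nominal disc strain, which a
real disc would resist nonlinearly. Passing tests therefore demonstrate
the correctness and internal consistency of the *pipeline* (mapping,
constraints, calibration, registration, statistics), not the biofidelity
of the constitutive choices.

## Mesh convergence

Convergence is assessed on nested meshes: each level uniformly splits
every tet4 of the same base mesh into 8 children before promotion to
tet10, so all levels share the identical polyhedral domain, and the
maximum RoI displacement magnitude is evaluated at the base level's RoI
nodes, which exist at the same indices in every nested level. Both
choices matter: re-meshing at a different edge length changes the
polygonal approximation of the cylinder *and* lets the max operator
sample nodes closer to the vertebra ends, which masquerades as
discretization error an order of magnitude above the real one. Soft
layers (discs, endplates) are meshed with at least two element layers
through the thickness, where the deformation gradient concentrates. The
default study (base edge 2.5 mm, one refinement, ~43k tet10 elements at
the fine level) changes the metric by < 0.1%; the fine level is at the
practical memory limit of the sparse direct factorization.

## Configuration, sizes and determinism

All stage parameters sit in one validated configuration with the study
defaults (nu_bone 0.3, nu_disc 0.1, 2 mm edge, 60 N target, 0.1% force
rule, Cook multiplier 4, R = registration RMSE); invalid values fail
with the offending field named. The default phantom solves ~8.6k tet10
elements in seconds; calibration re-solves the system ~7 times. Every
random element (cloud noise, mis-registration direction) derives from a
single seed, and the full pipeline is bit-reproducible for a fixed
configuration and seed.
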