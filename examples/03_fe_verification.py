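"""Verify the elasticity core against the rod formula.

A 10 mm cube with E = 100 MPa and nu = 0, base fixed, top surface tied
rigidly to a pilot node pushed down 0.1 mm: the axial reaction must be
E*A*delta/L = 100 * 100 * 0.1 / 10 = 100 N exactly.
"""

import numpy as np

import spinefe as sf
from spinefe.fe import equilibrium_residual

mesh = sf.box_mesh((10, 10, 10), edge=2.5, order=10)
mesh.E = np.full(mesh.n_elements, 100.0)
mesh.nu = np.zeros(mesh.n_elements)

z = mesh.nodes[:, 2]
pilot = np.array([5.0, 5.0, 12.0])
bcs = sf.BoundaryConditions(
    fixed_nodes=np.where(z < 1e-9)[0],
    tied_nodes=np.where(z > 10 - 1e-9)[0],
    pilot=pilot,
    pilot_motion=sf.RigidTransform(np.eye(3), [0, 0, -0.1], about=pilot),
)
sol = sf.apply_bcs_and_solve(mesh, bcs)

print(f"mesh: {mesh.n_elements} tet10 elements, {mesh.n_nodes} nodes")
print(f"axial reaction:       {sol.axial_resultant:+.6f} N   (rod formula: +100)")
print(f"equilibrium residual: {equilibrium_residual(sol):.2e}  (force balance)")
f_base, m_base = sf.reaction(sol, sol.fixed_nodes, about=pilot)
print(f"base reaction force:  {f_base.round(6)} N, moment about SP: {m_base.round(4)} N.mm")
# the reaction sign is the force the support exerts on the structure:
# compression pushes the base up (+z).
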