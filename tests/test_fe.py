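"""Elasticity core: operator properties, analytic solutions, equilibrium."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

import spinefe as sf
from spinefe.fe import assemble, equilibrium_residual
from tests.conftest import cube_bcs


def _single_tet(order=4):
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    mesh = sf.TetMesh(nodes, np.array([[0, 1, 2, 3]]))
    if order == 10:
        mesh = mesh.to_tet10()
    mesh.E = np.array([100.0])
    mesh.nu = np.array([0.25])
    return mesh


class TestAssemble:
    def test_single_tet4_symmetric_rank6(self):
        k = assemble(_single_tet()).toarray()
        assert k.shape == (12, 12)
        assert np.allclose(k, k.T)
        eigs = np.linalg.eigvalsh(k)
        assert (np.abs(eigs) < 1e-10).sum() == 6  # rigid-body null space

    def test_linearity_in_modulus(self):
        m = _single_tet()
        k1 = assemble(m).toarray()
        m.E = 2 * m.E
        assert np.allclose(assemble(m).toarray(), 2 * k1)

    def test_rigid_motion_has_zero_energy(self):
        """Linearized rigid motion (translation + skew field) has zero
        strain energy under the small-strain operator."""
        m = sf.box_mesh((4, 4, 4), edge=2.0, order=10)
        m.E = np.full(m.n_elements, 50.0)
        m.nu = np.full(m.n_elements, 0.3)
        k = assemble(m)
        w = np.array([[0, -2e-3, 1e-3], [2e-3, 0, -5e-4], [-1e-3, 5e-4, 0]])
        u = (m.nodes @ w.T + np.array([1.0, -2.0, 3.0])).ravel()
        energy = u @ (k @ u)
        assert abs(energy) < 1e-10 * np.abs(k.data).max()

    def test_inverted_element_reported(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        m = sf.TetMesh(nodes, np.array([[0, 2, 1, 3]]))
        m.E, m.nu = np.array([1.0]), np.array([0.3])
        with pytest.raises(ValueError, match="inverted"):
            assemble(m)


class TestPatchTest:
    @pytest.mark.parametrize("order", [4, 10])
    def test_affine_field_reproduced(self, order):
        """Affine displacement on the boundary is exact at interior nodes."""
        m = sf.box_mesh((4, 4, 4), edge=2.0, order=order)
        m.E = np.full(m.n_elements, 123.0)
        m.nu = np.full(m.n_elements, 0.3)
        a = np.array([[1e-3, 2e-4, 0], [0, -5e-4, 1e-4], [3e-4, 0, 2e-3]])
        k = assemble(m)
        on_b = np.any((np.abs(m.nodes) < 1e-12) | (np.abs(m.nodes - 4) < 1e-12), axis=1)
        bn = np.where(on_b)[0]
        dofs = (3 * bn[:, None] + np.arange(3)).ravel()
        g = (m.nodes[bn] @ a.T).ravel()
        ndof = 3 * m.n_nodes
        free = np.setdiff1d(np.arange(ndof), dofs)
        u = np.zeros(ndof)
        u[dofs] = g
        kc = k.tocsc()
        uf = spla.spsolve(kc[free][:, free], -(kc[:, dofs] @ g)[free])
        u[free] = uf
        exact = (m.nodes @ a.T).ravel()
        assert np.abs(u - exact).max() / np.abs(exact).max() < 1e-9

    def test_tet10_constant_strain(self):
        """A prescribed linear field produces the exact constant strain."""
        m = _single_tet(order=10)
        from spinefe.fe import _element_fields
        a = np.array([[1e-3, 0, 0], [0, -2e-3, 0], [0, 0, 5e-4]])
        strain, _ = _element_fields(m, m.nodes @ a.T)
        assert strain[0] == pytest.approx([1e-3, -2e-3, 5e-4, 0, 0, 0], abs=1e-15)


class TestSolve:
    def test_identity_motion_is_null(self, cube10):
        bcs = cube_bcs(cube10, dz=0.0)
        sol = sf.apply_bcs_and_solve(cube10, bcs)
        assert np.abs(sol.u).max() < 1e-12
        assert np.linalg.norm(sol.reaction_force) < 1e-9

    def test_cube_compression_rod_formula(self, cube10):
        """nu=0 cube: axial reaction = E*A*delta/L = 100 N exactly."""
        sol = sf.apply_bcs_and_solve(cube10, cube_bcs(cube10, dz=-0.1))
        assert abs(abs(sol.axial_resultant) - 100.0) / 100.0 < 1e-8
        assert equilibrium_residual(sol) < 1e-8

    def test_reactions_balance_base_and_pilot(self, cube10):
        sol = sf.apply_bcs_and_solve(cube10, cube_bcs(cube10, dz=-0.1))
        f_base, _ = sf.reaction(sol, sol.fixed_nodes)
        f_tied, _ = sf.reaction(sol, sol.tied_nodes)
        assert np.allclose(f_base + f_tied, 0.0, atol=1e-8)

    def test_tied_nodes_follow_rigid_motion_exactly(self, cube10):
        th = np.deg2rad(3.0)
        r = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        pilot = np.array([5.0, 5.0, 12.0])
        motion = sf.RigidTransform(r, [0.2, -0.1, -0.3], about=pilot)
        z = cube10.nodes[:, 2]
        bcs = sf.BoundaryConditions(np.where(z < 1e-9)[0], np.where(z > 10 - 1e-9)[0],
                                    pilot=pilot, pilot_motion=motion)
        sol = sf.apply_bcs_and_solve(cube10, bcs)
        expected = motion.apply(cube10.nodes[bcs.tied_nodes]) - cube10.nodes[bcs.tied_nodes]
        assert np.abs(sol.u[bcs.tied_nodes] - expected).max() < 1e-12

    def test_solution_invariant_under_renumbering(self, cube10):
        perm = np.random.default_rng(0).permutation(cube10.n_nodes)
        inv = np.argsort(perm)
        m2 = sf.TetMesh(cube10.nodes[perm], inv[cube10.elements],
                        E=cube10.E.copy(), nu=cube10.nu.copy())
        sol1 = sf.apply_bcs_and_solve(cube10, cube_bcs(cube10, dz=-0.1))
        sol2 = sf.apply_bcs_and_solve(m2, cube_bcs(m2, dz=-0.1))
        assert np.abs(sol2.u[inv] - sol1.u).max() < 1e-8 * np.abs(sol1.u).max()

    def test_non_orthonormal_rotation_rejected(self, cube10):
        bad = sf.RigidTransform(np.eye(3) + 1e-3, np.zeros(3),
                                about=np.array([5.0, 5.0, 12.0]))
        z = cube10.nodes[:, 2]
        bcs = sf.BoundaryConditions(np.where(z < 1e-9)[0], np.where(z > 10 - 1e-9)[0],
                                    pilot=np.array([5.0, 5.0, 12.0]), pilot_motion=bad)
        with pytest.raises(ValueError, match="orthonormal"):
            sf.apply_bcs_and_solve(cube10, bcs)

    def test_no_constraints_rejected(self, cube10):
        bcs = sf.BoundaryConditions(np.array([], dtype=int))
        with pytest.raises(ValueError, match="singular|constraints"):
            sf.apply_bcs_and_solve(cube10, bcs)

    def test_reaction_on_unconstrained_set_rejected(self, cube10):
        sol = sf.apply_bcs_and_solve(cube10, cube_bcs(cube10))
        interior = np.setdiff1d(np.arange(cube10.n_nodes),
                                np.concatenate([sol.fixed_nodes, sol.tied_nodes]))
        with pytest.raises(ValueError, match="not constrained"):
            sf.reaction(sol, interior[:3])

    def test_disjoint_sets_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            sf.BoundaryConditions(np.array([0, 1]), np.array([1, 2]),
                                  pilot=np.zeros(3),
                                  pilot_motion=sf.RigidTransform.identity())


def test_phantom_solve_equilibrium(phantom_default):
    """Global force balance on the full heterogeneous phantom solve."""
    assert equilibrium_residual(phantom_default["sol"]) < 1e-8
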