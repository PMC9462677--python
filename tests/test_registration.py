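"""Cloud triangulation, ICP registration, field transforms."""

import numpy as np
import pytest

import spinefe as sf
from spinefe.registration import pca_init, triangulate_cloud


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])


class TestTriangulateCloud:
    def test_square_gives_two_triangles(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        surf = triangulate_cloud(pts)
        assert len(surf.faces) == 2

    def test_regular_grid_triangle_count(self):
        n, m = 7, 5
        x, y = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
        pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(n * m)])
        surf = triangulate_cloud(pts)
        assert len(surf.faces) == 2 * (n - 1) * (m - 1)

    def test_cylindrical_patch_normals_outward(self):
        """90-degree cylinder patch: lifted normals near the radial direction."""
        theta = np.linspace(-np.pi / 4, np.pi / 4, 12)
        z = np.linspace(0, 10, 8)
        T, Z = np.meshgrid(theta, z)
        r = 20.0
        pts = np.column_stack([r * np.cos(T).ravel(), r * np.sin(T).ravel(), Z.ravel()])
        surf = triangulate_cloud(pts)
        v = pts[surf.faces]
        normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        centers = v.mean(axis=1)
        radial = centers * [1, 1, 0]
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.abs((normals * radial).sum(axis=1))
        assert (cosang > np.cos(np.deg2rad(60))).all()

    def test_folded_cloud_rejected(self):
        """A 300-degree cylinder shell is no height field over any plane."""
        theta = np.linspace(0, 5 * np.pi / 3, 40)
        z = np.linspace(0, 10, 8)
        T, Z = np.meshgrid(theta, z)
        pts = np.column_stack([10 * np.cos(T).ravel(), 10 * np.sin(T).ravel(), Z.ravel()])
        with pytest.raises(ValueError, match="projectable|folded"):
            triangulate_cloud(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            triangulate_cloud(np.zeros((2, 3)))


class TestApplyTransform:
    def test_identity_unchanged(self):
        fld = sf.SurfaceField(np.random.rand(5, 3), np.random.rand(5, 3))
        out = sf.apply_transform(fld, sf.RigidTransform.identity())
        assert np.array_equal(out.points, fld.points)
        assert np.array_equal(out.displacements, fld.displacements)

    def test_translation_leaves_vectors_bit_identical(self):
        fld = sf.SurfaceField(np.random.rand(5, 3), np.random.rand(5, 3))
        out = sf.apply_transform(fld, sf.RigidTransform(np.eye(3), [1.0, 2.0, 3.0]))
        assert np.array_equal(out.displacements, fld.displacements)
        assert np.allclose(out.points, fld.points + [1, 2, 3])

    def test_rotation_rotates_vectors(self):
        fld = sf.SurfaceField(np.zeros((1, 3)), np.array([[1.0, 0, 0]]))
        out = sf.apply_transform(fld, sf.RigidTransform(_rot_z(90), np.zeros(3)))
        assert np.allclose(out.displacements, [[0, 1, 0]], atol=1e-15)

    def test_vector_norms_preserved(self):
        rng = np.random.default_rng(3)
        fld = sf.SurfaceField(rng.normal(size=(20, 3)), rng.normal(size=(20, 3)))
        t = sf.RigidTransform(_rot_z(37.0), rng.normal(size=3))
        out = sf.apply_transform(fld, t)
        assert np.allclose(np.linalg.norm(out.displacements, axis=1),
                           np.linalg.norm(fld.displacements, axis=1))


class TestRegisterRigid:
    def test_exact_sample_registers_to_identity(self, phantom_coarse):
        mesh = phantom_coarse["mesh"]
        pts = mesh.nodes[mesh.surface_nodes()[::5]]
        res = sf.register_rigid(pts, mesh)
        assert res.rmse < 1e-9
        assert np.abs(res.transform.matrix() - np.eye(4)).max() < 1e-9

    def test_small_perturbation_recovered(self, phantom_coarse):
        mesh = phantom_coarse["mesh"]
        pts = mesh.nodes[mesh.surface_nodes()[::4]]
        t = sf.RigidTransform(_rot_z(1.0), [0.5, -0.2, 0.3])
        res = sf.register_rigid(t.apply(pts), mesh)
        assert res.rmse < 1e-6
        # recovered transform composed with the perturbation ~ identity
        assert np.abs(res.transform.compose(t).matrix() - np.eye(4)).max() < 1e-6

    def test_inverse_recovery_property(self, phantom_coarse):
        """register(apply(X, T), X) recovers T^-1 for rotations < 10 deg.

        The rotation axes tilt the patch out of the surface; a rotation
        about the cylinder axis beyond a few degrees slides the patch
        along its own (feature-poor) surface and is fundamentally weakly
        observable, so it is exercised only at small angle.
        """
        mesh = phantom_coarse["mesh"]
        spec = phantom_coarse["spec"]
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        fld = sf.SurfaceField(mesh.nodes[nodes], np.zeros((nodes.size, 3)))

        def rot_x(deg):
            a = np.deg2rad(deg)
            return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)],
                             [0, np.sin(a), np.cos(a)]])

        cases = [(_rot_z(3.0), [1.0, 0.5, -0.4]),
                 (rot_x(8.0), [-0.8, 0.3, 0.6]),
                 (rot_x(5.0) @ _rot_z(2.0), [0.4, -0.6, 0.2])]
        for r, shift in cases:
            t = sf.RigidTransform(r, shift)
            res = sf.register_rigid(sf.apply_transform(fld, t), mesh)
            err = np.abs(res.transform.matrix() - t.inverse().matrix()).max()
            assert err < 1e-6, err

    def test_error_stats_invariant_under_common_transform(self, phantom_coarse):
        mesh = phantom_coarse["mesh"]
        pts = mesh.nodes[mesh.surface_nodes()[::4]] + 0.05  # slight offset
        res1 = sf.register_rigid(pts, mesh)
        t = sf.RigidTransform(_rot_z(25.0), [4.0, -2.0, 7.0])
        mesh2 = sf.TetMesh(t.apply(mesh.nodes), mesh.elements.copy(),
                           dict(mesh.element_sets), mesh.E.copy(), mesh.nu.copy())
        res2 = sf.register_rigid(t.apply(pts), mesh2)
        assert res2.rmse == pytest.approx(res1.rmse, abs=1e-6)
        assert res2.mean_distance == pytest.approx(res1.mean_distance, abs=1e-6)

    def test_misregistered_synthetic_cloud_recovered(self, phantom_coarse):
        """End-to-end: a known mis-registration of the DIC-like cloud is
        undone to within a micrometre."""
        mesh, spec, sol = (phantom_coarse[k] for k in ("mesh", "spec", "sol"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        t = sf.RigidTransform(_rot_z(1.0), [0.5, -0.3, 0.2])
        fld = sf.synth_dic_cloud(sol, nodes, spec, noise=False, misregistration=t)
        res = sf.register_rigid(fld, mesh)
        assert np.abs(res.transform.compose(t).matrix() - np.eye(4)).max() < 1e-3


def test_pca_init_roughly_aligns(phantom_coarse):
    mesh = phantom_coarse["mesh"]
    pts = mesh.nodes[mesh.surface_nodes()[::3]]
    t = sf.RigidTransform(_rot_z(30.0), [8.0, -5.0, 3.0])
    init = pca_init(t.apply(pts), mesh.nodes[mesh.surface_nodes()])
    moved = init.apply(t.apply(pts))
    rms = np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1)))
    assert rms < 5.0  # coarse alignment good enough to seed ICP
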