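"""Validation metrics: spherical averaging, Cook's filter, regression,
error fields, Bland-Altman."""

import dataclasses

import numpy as np
import pytest

import spinefe as sf
from spinefe.validation import PairedSamples, ValidationConfig


def _pairs(u_dic, u_fem, pos=None):
    u_dic = np.atleast_2d(u_dic)
    u_fem = np.atleast_2d(u_fem)
    n = u_dic.shape[0]
    if pos is None:
        pos = np.zeros((n, 3))
    return PairedSamples(np.arange(n), pos, np.asarray(u_fem, float),
                         np.asarray(u_dic, float), 0)


class TestPairAndAverage:
    def test_coincident_point_returns_its_vector(self, phantom_coarse):
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        fld = sf.synth_dic_cloud(sol, nodes, spec, noise=False)
        pairs = sf.pair_and_average(nodes, sol, fld, ValidationConfig(radius=0.5))
        assert pairs.n_dropped == 0
        assert np.allclose(pairs.u_dic, pairs.u_fem, atol=1e-14)

    def test_two_points_average(self, phantom_coarse):
        sol = phantom_coarse["sol"]
        node = sf.roi_surface_nodes(phantom_coarse["mesh"],
                                    phantom_coarse["spec"], "bone_L3")[:1]
        x = sol.mesh.nodes[node[0]]
        fld = sf.SurfaceField(np.vstack([x + [0.1, 0, 0], x - [0.1, 0, 0]]),
                              np.array([[1.0, 0, 0], [3.0, 0, 0]]))
        pairs = sf.pair_and_average(node, sol, fld, ValidationConfig(radius=0.5))
        assert np.allclose(pairs.u_dic[0], [2.0, 0, 0])

    def test_constant_field_any_radius(self, phantom_coarse):
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L2")
        fld = sf.SurfaceField(mesh.nodes[nodes],
                              np.tile([0.5, -0.25, 1.0], (nodes.size, 1)))
        for r in (0.5, 2.0, 5.0):
            pairs = sf.pair_and_average(nodes, sol, fld, ValidationConfig(radius=r))
            assert np.allclose(pairs.u_dic, [0.5, -0.25, 1.0])

    def test_empty_pairing_raises(self, phantom_coarse):
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        far = sf.SurfaceField(mesh.nodes[nodes] + 500.0, np.zeros((nodes.size, 3)))
        with pytest.raises(ValueError, match="radius"):
            sf.pair_and_average(nodes, sol, far, ValidationConfig(radius=0.5))


class TestCooksFilter:
    def test_perfect_line_removes_nothing(self):
        x = np.arange(10.0)
        assert sf.cooks_filter(x, 2 * x + 1).all()

    def test_influential_point_removed(self):
        # leave-one-out oracle: the (10, 0) point dominates the fit
        x = np.array([1.0, 2, 3, 4, 10])
        y = np.array([1.0, 2, 3, 4, 0])
        mask = sf.cooks_filter(x, y, multiplier=4.0)
        assert not mask[-1]
        assert mask[:4].all()

    def test_mask_bookkeeping(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.1, size=30)
        mask = sf.cooks_filter(x, y)
        assert mask.shape == (30,)
        assert mask.sum() + (~mask).sum() == 30

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            mask = sf.cooks_filter(np.arange(3.0), np.arange(3.0))
        assert mask.all()


class TestRegressComponent:
    def test_identity_fields(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(20, 3))
        m = sf.regress_component(_pairs(u, u), "SI")
        assert m.r2 == pytest.approx(1.0)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.0, abs=1e-12)
        assert m.n_outliers_removed == 0

    def test_pct_rmse_scale_invariant(self):
        rng = np.random.default_rng(2)
        u_dic = rng.normal(size=(30, 3))
        u_fem = u_dic + rng.normal(scale=0.05, size=(30, 3))
        m1 = sf.regress_component(_pairs(u_dic, u_fem), "AP")
        m2 = sf.regress_component(_pairs(7.0 * u_dic, 7.0 * u_fem), "AP")
        assert m2.pct_rmse == pytest.approx(m1.pct_rmse, rel=1e-9)

    def test_zero_variance_rejected(self):
        u = np.tile([1.0, 1.0, 1.0], (10, 1))
        with pytest.raises(ValueError, match="variance"):
            sf.regress_component(_pairs(u, u + 0.1), "RL")

    def test_small_displacement_guard_counts(self):
        u_dic = np.array([[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0],
                          [4.0, 0, 0], [1e-5, 0, 0]])
        u_fem = u_dic * 1.01
        m = sf.regress_component(_pairs(u_dic, u_fem), "RL",
                                 ValidationConfig(radius=1.0, cook_multiplier=100.0))
        assert m.n_guarded == 1


class TestErrorFields:
    def test_hand_values(self):
        # measured (1,1,1), predicted (0.9,1.1,1.0): errors (0.1,0.1,0)
        pairs = _pairs([1.0, 1.0, 1.0], [0.9, 1.1, 1.0])
        err = np.abs(pairs.u_dic - pairs.u_fem)[0]
        assert np.allclose(err, [0.1, 0.1, 0.0])
        assert np.allclose(100 * err / np.abs(pairs.u_dic[0]), [10.0, 10.0, 0.0])
        assert sf.diff_field(pairs)[0] == pytest.approx(0.14142136, abs=1e-7)

    def test_zero_error(self):
        pairs = _pairs([1.0, 2, 3], [1.0, 2, 3])
        assert sf.diff_field(pairs)[0] == 0.0

    def test_diff_dominates_components(self):
        rng = np.random.default_rng(3)
        pairs = _pairs(rng.normal(size=(50, 3)), rng.normal(size=(50, 3)))
        diff = sf.diff_field(pairs)
        err = np.abs(pairs.u_dic - pairs.u_fem)
        assert (diff[:, None] >= err - 1e-12).all()


class TestBlandAltman:
    def test_identical_fields(self):
        u = np.random.rand(10, 3)
        ba = sf.bland_altman(_pairs(u, u), "AP")
        assert ba.bias == 0.0
        assert np.allclose(ba.differences, 0.0)

    def test_constant_offset(self):
        u = np.random.rand(10, 3)
        ba = sf.bland_altman(_pairs(u + 0.25, u), "RL")
        assert ba.bias == pytest.approx(0.25)
        assert ba.loa_low == pytest.approx(0.25)
        assert ba.loa_high == pytest.approx(0.25)

    def test_heteroscedastic_trend_recovered(self):
        """Noise proportional to magnitude shows up as |diff| growing with mean."""
        rng = np.random.default_rng(4)
        mag = np.linspace(0.5, 5.0, 400)
        u_dic = np.column_stack([mag, np.zeros(400), np.zeros(400)])
        u_fem = u_dic.copy()
        u_fem[:, 0] += rng.normal(scale=0.05 * mag)
        ba = sf.bland_altman(_pairs(u_dic, u_fem))
        r = np.corrcoef(ba.means, np.abs(ba.differences))[0, 1]
        assert r > 0.2


class TestEndToEnd:
    def test_noise_free_closed_loop(self, phantom_coarse):
        """Cloud sampled from the solution itself: perfect agreement."""
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        rois, flds = {}, {}
        for roi, vert in (("RoI_L2", "bone_L2"), ("RoI_L3", "bone_L3")):
            nodes = sf.roi_surface_nodes(mesh, spec, vert)
            rois[roi] = nodes
            flds[roi] = sf.synth_dic_cloud(sol, nodes, spec, noise=False,
                                           roi_label=roi)
        rep = sf.validate_roi(sol, flds, rois, ValidationConfig(radius=0.53))
        for roi, comps in rep.metrics.items():
            for comp, m in comps.items():
                assert m.r2 == pytest.approx(1.0, abs=1e-9)
                assert m.rmse <= 1e-9
                assert m.n_outliers_removed == 0

    def test_metrics_invariant_under_common_translation(self, phantom_coarse):
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        rng = np.random.default_rng(5)
        fld = sf.synth_dic_cloud(sol, nodes, spec, rng=rng, noise=True)
        cfg = ValidationConfig(radius=0.53)
        m1 = sf.regress_component(sf.pair_and_average(nodes, sol, fld, cfg), "SI", cfg)

        shift = np.array([10.0, -20.0, 5.0])
        mesh2 = sf.TetMesh(mesh.nodes + shift, mesh.elements.copy(),
                           dict(mesh.element_sets), mesh.E.copy(), mesh.nu.copy())
        sol2 = dataclasses.replace(sol, mesh=mesh2)
        fld2 = sf.SurfaceField(fld.points + shift, fld.displacements.copy())
        m2 = sf.regress_component(sf.pair_and_average(nodes, sol2, fld2, cfg), "SI", cfg)
        assert m2.r2 == pytest.approx(m1.r2, abs=1e-12)
        assert m2.rmse == pytest.approx(m1.rmse, abs=1e-12)

    def test_diff_field_invariant_under_common_rotation(self, phantom_coarse):
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        rng = np.random.default_rng(6)
        fld = sf.synth_dic_cloud(sol, nodes, spec, rng=rng, noise=True)
        cfg = ValidationConfig(radius=0.53)
        d1 = sf.diff_field(sf.pair_and_average(nodes, sol, fld, cfg))

        a = np.deg2rad(30)
        r = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        t = sf.RigidTransform(r, [3.0, 1.0, -2.0])
        mesh2 = sf.TetMesh(t.apply(mesh.nodes), mesh.elements.copy(),
                           dict(mesh.element_sets), mesh.E.copy(), mesh.nu.copy())
        sol2 = dataclasses.replace(sol, mesh=mesh2, u=t.rotate_vectors(sol.u))
        fld2 = sf.apply_transform(fld, t)
        d2 = sf.diff_field(sf.pair_and_average(nodes, sol2, fld2, cfg))
        assert np.allclose(d2, d1, atol=1e-10)

    def test_report_table_shape(self, phantom_coarse):
        sol, mesh, spec = (phantom_coarse[k] for k in ("sol", "mesh", "spec"))
        nodes = sf.roi_surface_nodes(mesh, spec, "bone_L3")
        fld = sf.synth_dic_cloud(sol, nodes, spec, noise=False, roi_label="RoI_L3")
        rep = sf.validate_roi(sol, {"RoI_L3": fld}, {"RoI_L3": nodes},
                              ValidationConfig(radius=0.53))
        frame = rep.to_frame()
        assert ("RoI_L3", "SI") in frame.columns
        assert "RMSE %" in frame.index
        assert {"Diff", "Error_RL", "ErrorPct_SI"} <= set(rep.pointwise["RoI_L3"].columns)
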