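"""Triangulation, rigid-fit and shift-pipeline tests."""

import numpy as np
import pytest

from conftest import random_qa_pose
from isoqa.errors import (
    ConditioningError,
    DegenerateConfigurationError,
    UnderdeterminedError,
)
from isoqa.geometry import Pose6D, apply_pose, invert_pose, project_to_imager
from isoqa.phantom import MV_FIELD, render_planar, render_volume
from isoqa.pose import (
    ProjectionObservation,
    detect_bb_observations,
    planar_isocenter_shift,
    register_cbct_to_ct,
    rigid_fit,
    triangulate_point,
)

CARDINALS = (0.0, 90.0, 180.0, 270.0)


def observe(point, geom, gantries=CARDINALS, label="p"):
    return [ProjectionObservation(
        label=label, imager_point=project_to_imager(point, geom.replace(gantry_deg=g)),
        geom=geom.replace(gantry_deg=g)) for g in gantries]


class TestTriangulation:
    def test_recovers_point_from_cardinal_views(self, geom):
        point = np.array([5.0, -3.0, 7.0])
        est, resid = triangulate_point(observe(point, geom))
        assert np.allclose(est, point, atol=1e-6)
        assert resid < 1e-9

    def test_single_observation_underdetermined(self, geom):
        with pytest.raises(UnderdeterminedError):
            triangulate_point(observe([1.0, 2.0, 3.0], geom, gantries=(0.0,)))

    def test_nearly_parallel_rays_rejected(self, geom):
        with pytest.raises(ConditioningError):
            triangulate_point(observe([1.0, 2.0, 3.0], geom, gantries=(0.0, 5.0)))

    def test_opposed_views_rejected_as_parallel_lines(self, geom):
        # gantry 0 and 180 look along the same line: no lateral information
        with pytest.raises(ConditioningError):
            triangulate_point(observe([0.0, 2.0, 0.0], geom, gantries=(0.0, 180.0)))

    def test_noise_robustness(self, geom, rng):
        # +-0.1 mm uniform perturbations on the imager: point within 0.2 mm
        point = np.array([5.0, -3.0, 7.0])
        for _ in range(100):
            obs = [ProjectionObservation(
                label="p",
                imager_point=o.imager_point + rng.uniform(-0.1, 0.1, 2),
                geom=o.geom) for o in observe(point, geom)]
            est, _ = triangulate_point(obs)
            assert np.linalg.norm(est - point) < 0.2

    def test_residual_zero_iff_consistent(self, geom, rng):
        point = rng.uniform(-30, 30, 3)
        _, resid = triangulate_point(observe(point, geom))
        assert resid <= 1e-9
        obs = observe(point, geom)
        obs[0] = ProjectionObservation(label="p",
                                       imager_point=obs[0].imager_point + 0.5,
                                       geom=obs[0].geom)
        _, resid2 = triangulate_point(obs)
        assert resid2 > 1e-3


NOMINAL = [("central", (0.0, 0.0, 0.0)), ("a1", (20.0, 12.0, -16.0)),
           ("a2", (-24.0, -18.0, 10.0)), ("a3", (14.0, -26.0, 22.0)),
           ("a4", (-20.0, 35.0, 20.0))]


class TestRigidFit:
    def test_identity(self):
        res = rigid_fit(NOMINAL, NOMINAL)
        assert np.allclose(res.pose.as_array(), 0.0, atol=1e-12)
        assert res.residual_rms_mm < 1e-12

    def test_recovers_injected_transform(self):
        pose = Pose6D(vrt_mm=2.0, lng_mm=-0.5, lat_mm=1.0,
                      pitch_deg=0.5, roll_deg=-0.3, rtn_deg=1.0)
        moved = [(lab, apply_pose(pose, p)) for lab, p in NOMINAL]
        res = rigid_fit(moved, NOMINAL)
        assert np.allclose(res.pose.as_array(), pose.as_array(), atol=1e-9)
        assert res.residual_rms_mm < 1e-9

    def test_collinear_points_degenerate(self):
        line = [(f"p{i}", (float(i), 0.0, 0.0)) for i in range(4)]
        with pytest.raises(DegenerateConfigurationError):
            rigid_fit(line, line)

    def test_too_few_points(self):
        two = NOMINAL[:2]
        with pytest.raises(UnderdeterminedError):
            rigid_fit(two, two)

    def test_mirrored_set_still_proper_rotation(self):
        # near-coplanar points with a mirrored copy: the unconstrained
        # orthogonal fit would return a reflection (det -1); ours must not
        nominal = [("a", (10.0, 0.0, 0.1)), ("b", (-10.0, 0.0, -0.1)),
                   ("c", (0.0, 10.0, 0.05)), ("d", (0.0, -10.0, 0.0)),
                   ("e", (5.0, 5.0, -0.05))]
        mirrored = [(lab, (p[0], p[1], -p[2])) for lab, p in nominal]
        m = np.array([p for _, p in mirrored], float)
        n = np.array([p for _, p in nominal], float)
        h = (n - n.mean(0)).T @ (m - m.mean(0))
        u, _, vt = np.linalg.svd(h)
        assert np.linalg.det(vt.T @ u.T) < 0  # naive fit would reflect
        res = rigid_fit(mirrored, nominal)
        assert np.linalg.det(res.pose.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_grid_local_optimality(self, rng):
        # fitted pose beats every +-0.01-grid neighbor of the 6D objective
        pose = Pose6D(0.21, -0.33, 0.12, 0.24, -0.17, 0.31)
        moved = [(lab, apply_pose(pose, p) + rng.normal(0, 0.05, 3))
                 for lab, p in NOMINAL]
        res = rigid_fit(moved, NOMINAL)

        m = np.array([p for _, p in moved])
        n = np.array([p for _, p in NOMINAL])

        def objective(arr):
            cand = Pose6D(*arr)
            return np.sum((apply_pose(cand, n) - m) ** 2)

        best = objective(res.pose.as_array())
        step = 0.01
        neighbors = [res.pose.as_array() + step * delta
                     for delta in np.vstack([np.eye(6), -np.eye(6)])]
        neighbors += [res.pose.as_array()
                      + step * rng.integers(-1, 2, size=6)
                      for _ in range(50)]
        for cand in neighbors:
            assert objective(cand) >= best - 1e-12


class TestPlanarPipeline:
    def test_null_case(self, phantom, geom):
        imgs = [render_planar(phantom, Pose6D(), geom.replace(gantry_deg=g),
                              MV_FIELD) for g in CARDINALS]
        res = planar_isocenter_shift(imgs, phantom)
        assert np.all(np.abs(res.pose.as_array()) < 0.05)

    def test_recovers_injected_shift(self, phantom, geom):
        truth = Pose6D(lat_mm=0.8, rtn_deg=0.3)
        imgs = [render_planar(phantom, invert_pose(truth),
                              geom.replace(gantry_deg=g), MV_FIELD)
                for g in CARDINALS]
        res = planar_isocenter_shift(imgs, phantom)
        err = np.abs(res.pose.as_array() - truth.as_array())
        assert np.all(err[:3] < 0.1)   # translations, mm
        assert np.all(err[3:] < 0.1)   # rotations, deg

    def test_composition_identity(self, phantom, geom):
        # the pipeline equals rigid_fit applied to independently
        # triangulated centroids of the same observations
        truth = Pose6D(vrt_mm=0.4, rtn_deg=-0.2)
        imgs = [render_planar(phantom, invert_pose(truth),
                              geom.replace(gantry_deg=g), MV_FIELD)
                for g in CARDINALS]
        res = planar_isocenter_shift(imgs, phantom)

        by_label = {}
        for img in imgs:
            for o in detect_bb_observations(img, phantom):
                by_label.setdefault(o.label, []).append(o)
        measured = [(lab, triangulate_point(obs)[0])
                    for lab, obs in by_label.items()]
        manual = rigid_fit(measured, list(phantom.positions().items()))
        manual_shift = invert_pose(manual.pose)
        assert np.allclose(res.pose.as_array(), manual_shift.as_array(),
                           atol=1e-9)


class TestCBCTRegistration:
    def test_same_volume_zero_shift(self, phantom):
        ct = render_volume(phantom, Pose6D(), 1.0)
        res = register_cbct_to_ct(ct, ct, phantom)
        assert np.all(np.abs(res.pose.as_array()) < 1e-9)
        assert not res.quality_warning

    def test_recovers_shift_across_voxel_sizes(self, phantom):
        # CT at fine spacing, CBCT at coarser spacing, truth recovered
        truth = Pose6D(lng_mm=1.0, rtn_deg=0.2)
        ct = render_volume(phantom, Pose6D(), 0.6)
        cbct = render_volume(phantom, invert_pose(truth), 1.0)
        res = register_cbct_to_ct(cbct, ct, phantom)
        err = np.abs(res.pose.as_array() - truth.as_array())
        assert np.all(err[:3] < 0.2)
        assert np.all(err[3:] < 0.1)
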