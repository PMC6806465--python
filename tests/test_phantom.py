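"""Phantom spec and synthetic renderer tests."""

import numpy as np
import pytest

from conftest import random_qa_pose
from isoqa.errors import DomainError, GeometryError
from isoqa.geometry import Pose6D, apply_pose, project_to_imager
from isoqa.phantom import (
    KV_FIELD,
    MV_FIELD,
    WL_FIELD,
    FieldAperture,
    PhantomSpec,
    SessionTruth,
    default_phantom,
    render_planar,
    render_volume,
    simulate_session,
)
from isoqa.segmentation import contour_components, field_region, filter_by_area


class TestPhantomSpec:
    def test_default_has_five_bbs(self, phantom):
        assert len(phantom.bbs) == 5

    def test_central_bb_at_origin(self, phantom):
        assert np.allclose(phantom.positions()["central"], 0.0)

    def test_max_off_center_distance_45mm(self, phantom):
        dists = [np.linalg.norm(p) for lab, p in phantom.positions().items()
                 if lab != "central"]
        assert max(dists) == pytest.approx(45.0)
        assert min(dists) >= 25.0

    def test_bb_diameters_7p5mm(self, phantom):
        assert set(phantom.diameters().values()) == {7.5}

    def test_off_center_layout_asymmetric(self, phantom):
        # no two BBs share a coordinate on any axis: a projection cannot
        # confuse labels
        pos = np.array(list(phantom.positions().values()))
        for axis in range(3):
            vals = pos[:, axis]
            assert len(np.unique(vals)) == len(vals)

    def test_invalid_specs_rejected(self):
        with pytest.raises(DomainError):
            PhantomSpec(bbs=(("central", (0, 0, 0), 7.5),
                             ("x", (1.0, 0, 0), 7.5)))  # overlapping
        with pytest.raises(DomainError):
            PhantomSpec(bbs=(("a", (0, 0, 0), 7.5),))  # no central label
        with pytest.raises(DomainError):
            PhantomSpec(bbs=(("central", (0, 0, 0), 7.5),
                             ("far", (80, 0, 0), 7.5)))  # outside cube


class TestRenderPlanar:
    def test_deterministic_for_fixed_seed(self, phantom, geom):
        a = render_planar(phantom, Pose6D(), geom, WL_FIELD,
                          noise_sigma=0.01, seed=42)
        b = render_planar(phantom, Pose6D(), geom, WL_FIELD,
                          noise_sigma=0.01, seed=42)
        assert np.array_equal(a.pixels, b.pixels)
        c = render_planar(phantom, Pose6D(), geom, WL_FIELD,
                          noise_sigma=0.01, seed=43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_central_bb_minimum_at_projection(self, phantom, geom):
        img = render_planar(phantom, Pose6D(), geom, WL_FIELD)
        # darkest pixel well inside the field (away from the penumbra ring)
        # should be the central-BB projection
        u, v = img.mm_grids()
        interior = (np.abs(u) < 10) & (np.abs(v) < 10)
        r, c = np.unravel_index(
            np.argmin(np.where(interior, img.pixels, np.inf)),
            img.pixels.shape)
        found = img.pixel_to_mm(r, c)
        expected = project_to_imager([0, 0, 0], geom)
        # nearest pixel center: within half a pixel on each imager axis
        assert np.all(np.abs(found - expected) <= 0.5 * geom.pixel_pitch_mm + 1e-9)

    def test_wl_field_edges_at_pm_18_75_mm(self, phantom, geom):
        img = render_planar(phantom, Pose6D(), geom, WL_FIELD)
        fm = field_region(img)
        left, right, bottom, top = fm.edge_positions
        assert left == pytest.approx(-18.75, abs=0.1)
        assert right == pytest.approx(18.75, abs=0.1)
        assert bottom == pytest.approx(-18.75, abs=0.1)
        assert top == pytest.approx(18.75, abs=0.1)

    def test_field_exceeding_imager_rejected(self, phantom, geom):
        with pytest.raises(GeometryError):
            render_planar(phantom, Pose6D(), geom, FieldAperture(400.0, 400.0))

    def test_open_field_bright_bbs_dark(self, phantom, geom):
        img = render_planar(phantom, Pose6D(), geom, WL_FIELD)
        center_px = img.mm_to_pixel(0.0, 0.0).astype(int)
        corner_px = img.mm_to_pixel(15.0, 15.0).astype(int)
        assert (img.pixels[corner_px[0], corner_px[1]]
                > img.pixels[center_px[0], center_px[1]])

    def test_projective_consistency_random_poses(self, phantom, geom, rng):
        # detected BB centers track the divergent projection of the posed
        # BB positions over random QA-regime poses
        for _ in range(100):
            pose = random_qa_pose(rng)
            gantry = float(rng.choice([0.0, 90.0, 180.0, 270.0]))
            g = geom.replace(gantry_deg=gantry)
            img = render_planar(phantom, pose, g, KV_FIELD)
            regions = contour_components(img)
            r_px = 3.75 * g.magnification / g.pixel_pitch_mm
            regions = filter_by_area(regions, np.pi * r_px**2)
            assert len(regions) == 5
            expected = [project_to_imager(apply_pose(pose, p), g)
                        for p in phantom.positions().values()]
            for e in expected:
                d = min(np.linalg.norm(r.centroid - e) for r in regions)
                assert d < 0.5 * g.pixel_pitch_mm


class TestRenderVolume:
    def test_contrast_ordering(self, phantom):
        vol = render_volume(phantom, Pose6D(), 1.5)
        # BB voxels strictly brighter than plastic: compare peak vs median
        assert vol.voxels.max() > np.median(vol.voxels) > vol.voxels.min()
        assert vol.voxels.max() == pytest.approx(phantom.bb_intensity, rel=0.01)

    def test_central_bb_centroid_accuracy(self, phantom):
        vox = 1.0
        vol = render_volume(phantom, Pose6D(), vox)
        plastic = float(np.median(vol.voxels))
        thr = plastic + 0.5 * (vol.voxels.max() - plastic)
        from scipy import ndimage
        mask = vol.voxels > thr
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        best = None
        for idx in range(1, n + 1):
            w = np.where(labels == idx, vol.voxels - thr, 0)
            com = vol.index_to_world(ndimage.center_of_mass(w))
            if best is None or np.linalg.norm(com) < np.linalg.norm(best):
                best = com
        assert np.linalg.norm(best - 0.0) < 0.1 * vox

    def test_lng_shift_moves_all_centroids(self, phantom):
        vox = 1.0
        a = render_volume(phantom, Pose6D(), vox)
        b = render_volume(phantom, Pose6D(lng_mm=2.0), vox)
        from isoqa.segmentation import bb_centroids_3d
        nominal = list(phantom.positions().items())
        ca = {r.label: r.centroid for r in bb_centroids_3d(a, nominal)}
        shifted = [(lab, p + np.array([0, 2.0, 0])) for lab, p in nominal]
        cb = {r.label: r.centroid for r in bb_centroids_3d(b, shifted)}
        for lab in ca:
            delta = cb[lab] - ca[lab]
            assert np.allclose(delta, [0, 2.0, 0], atol=0.1 * vox)

    def test_cube_exceeding_extent_rejected(self, phantom):
        with pytest.raises(GeometryError):
            render_volume(phantom, Pose6D(), 1.0, margin_mm=-200.0)

    def test_deterministic(self, phantom):
        a = render_volume(phantom, Pose6D(), 2.0, noise_sigma=0.001, seed=9)
        b = render_volume(phantom, Pose6D(), 2.0, noise_sigma=0.001, seed=9)
        assert np.array_equal(a.voxels, b.voxels)


@pytest.fixture(scope="module")
def session():
    return simulate_session(
        truth=SessionTruth(mv=Pose6D(lat_mm=0.5)),
        ct_voxel_mm=2.0, cbct_voxel_mm=2.0, seed=11)


class TestSimulateSession:
    def test_image_counts(self, session):
        assert len(session.planar_mv) == 4
        assert len(session.planar_kv) == 4
        assert len(session.wl_images) == 12

    def test_ground_truth_retained(self, session):
        assert session.truth.mv.lat_mm == 0.5
        assert session.truth.kv == Pose6D()
        assert session.seed == 11

    def test_wl_geometries_match_template(self, session):
        from isoqa.plan import build_sequence
        cps = build_sequence("winston_lutz").control_points
        for img, cp in zip(session.wl_images, cps):
            assert img.geom.gantry_deg == cp.gantry_deg
            assert img.geom.collimator_deg == cp.collimator_deg
            assert img.geom.couch_deg == cp.couch_deg
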