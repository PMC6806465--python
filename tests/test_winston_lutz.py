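"""Ball-and-field deviation and radiation-isocenter fit tests."""

import numpy as np
import pytest

from isoqa.errors import UnderdeterminedError
from isoqa.geometry import (
    BeamGeometry,
    Pose6D,
    imager_axes,
    imager_to_iso_plane,
    project_to_imager,
)
from isoqa.phantom import WL_FIELD, render_planar
from isoqa.plan import build_sequence
from isoqa.winston_lutz import (
    WLImageResult,
    fit_radiation_isocenter,
    wl_image_deviation,
    wl_summary,
)


def synthetic_results(geom, axis_offset=(0.0, 0.0, 0.0), bb=(0.0, 0.0, 0.0),
                      jitter=None, rng=None):
    """Ideal WLImageResults for the 12-image template: the beam axis passes
    through ``axis_offset`` (+ optional per-image jitter), the BB sits at
    ``bb`` and rides couch rotations."""
    out = []
    axis_offset = np.asarray(axis_offset, float)
    bb = np.asarray(bb, float)
    for cp in build_sequence("winston_lutz").control_points:
        g = geom.replace(gantry_deg=cp.gantry_deg,
                         collimator_deg=cp.collimator_deg,
                         couch_deg=cp.couch_deg)
        # the beam axis passes through the 3D offset point: its imager
        # trace is the divergent projection of that point
        field = imager_to_iso_plane(project_to_imager(axis_offset, g), g)
        if jitter is not None:
            field = field + rng.uniform(-jitter, jitter, 2)
        a = np.radians(cp.couch_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        bb_now = rot @ bb
        bb_uv = imager_to_iso_plane(project_to_imager(bb_now, g), g)
        out.append(WLImageResult(geom=g, field_center_iso=field,
                                 bb_center_iso=bb_uv))
    return out


class TestWLImageDeviation:
    def test_null_case(self, phantom, geom):
        img = render_planar(phantom, Pose6D(), geom, WL_FIELD)
        res = wl_image_deviation(img, phantom)
        assert np.all(np.abs(res.deviation_2d) < 0.05)

    def test_demagnification_of_field_offset(self, phantom, geom):
        # field shifted 1.0 mm at iso = 1.5 mm on the imager; BB on axis
        img = render_planar(phantom, Pose6D(), geom, WL_FIELD,
                            field_shift_iso=(1.0, 0.0))
        res = wl_image_deviation(img, phantom)
        assert res.deviation_2d[0] == pytest.approx(1.0, abs=0.05)

    def test_bb_displacement_sign(self, phantom, geom):
        # BB moved -0.5 mm LAT at gantry 0 -> deviation +0.5 mm along u
        img = render_planar(phantom, Pose6D(lat_mm=-0.5), geom, WL_FIELD)
        res = wl_image_deviation(img, phantom)
        assert res.deviation_2d[0] == pytest.approx(0.5, abs=0.05)

    def test_deviation_norm_consistent(self, phantom, geom):
        img = render_planar(phantom, Pose6D(), geom, WL_FIELD,
                            field_shift_iso=(0.3, -0.4))
        res = wl_image_deviation(img, phantom)
        assert res.deviation_norm_mm == pytest.approx(
            np.linalg.norm(res.deviation_2d))


class TestFitRadiationIsocenter:
    def test_all_zero_deviations(self, geom):
        wl = fit_radiation_isocenter(synthetic_results(geom))
        assert np.allclose(wl.radiation_isocenter, 0.0, atol=1e-9)
        assert wl.gantry_walkout_mm == pytest.approx(0.0, abs=1e-9)
        assert wl.collimator_walkout_mm == pytest.approx(0.0, abs=1e-9)
        assert wl.couch_walkout_mm == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("offset", [(0.3, 0.0, 0.0), (0.0, -0.4, 0.25),
                                        (1.0, 0.6, -0.8)])
    def test_constant_axis_offset_recovered(self, geom, offset):
        wl = fit_radiation_isocenter(synthetic_results(geom, axis_offset=offset))
        assert np.allclose(wl.radiation_isocenter, offset, atol=1e-6)
        assert wl.gantry_walkout_mm < 1e-6

    def test_phantom_shift_is_iso_minus_bb(self, geom):
        wl = fit_radiation_isocenter(
            synthetic_results(geom, axis_offset=(0.3, 0.0, 0.0),
                              bb=(0.1, -0.2, 0.05)))
        assert np.allclose(wl.phantom_shift, [0.2, 0.2, -0.05], atol=1e-6)
        assert np.allclose(wl.phantom_shift,
                           wl.radiation_isocenter - wl.bb_position, atol=1e-9)

    def test_jittered_fit_matches_grid_search(self, geom, rng):
        # brute-force grid at 0.005 mm step around the fit must not improve
        res = synthetic_results(geom, jitter=0.2, rng=rng)
        wl = fit_radiation_isocenter(res)
        rays = [r.field_ray() for r in res]

        def cost(p):
            return sum(ray.distance_to(p) ** 2 for ray in rays)

        step = 0.005
        offsets = np.arange(-10, 11) * step
        grid = np.stack(np.meshgrid(offsets, offsets, offsets,
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        costs = np.array([cost(wl.radiation_isocenter + d) for d in grid])
        best = grid[np.argmin(costs)]
        assert np.all(np.abs(best) <= step + 1e-12)

    def test_translation_equivariance(self, geom, rng):
        res = synthetic_results(geom, jitter=0.15, rng=rng)
        wl = fit_radiation_isocenter(res)
        shift = np.array([1.0, -2.0, 0.5])
        rays = [r.field_ray() for r in res]
        a = np.zeros((3, 3))
        b = np.zeros(3)
        for ray in rays:
            proj = np.eye(3) - np.outer(ray.direction, ray.direction)
            a += proj
            b += proj @ (ray.origin + shift)
        moved = np.linalg.solve(a, b)
        assert np.allclose(moved, wl.radiation_isocenter + shift, atol=1e-9)

    def test_couch_only_jitter_hits_couch_walkout(self, geom, rng):
        res = synthetic_results(geom)
        out = []
        for r in res:
            if r.geom.couch_deg != 0.0:
                r = WLImageResult(geom=r.geom,
                                  field_center_iso=r.field_center_iso
                                  + rng.uniform(0.1, 0.2, 2),
                                  bb_center_iso=r.bb_center_iso)
            out.append(r)
        wl = fit_radiation_isocenter(out)
        assert wl.couch_walkout_mm > 0.05
        assert wl.couch_walkout_mm > wl.gantry_walkout_mm

    def test_underdetermined_geometry_rejected(self, geom):
        res = synthetic_results(geom)[:2]
        with pytest.raises(UnderdeterminedError):
            fit_radiation_isocenter(res)


class TestWLSummary:
    def test_zero_shift_zero_magnitude(self, geom):
        wl = fit_radiation_isocenter(synthetic_results(geom))
        assert wl_summary(wl)["magnitude_3d_mm"] == pytest.approx(0.0, abs=1e-9)

    def test_three_four_five_triangle(self, geom):
        wl = fit_radiation_isocenter(
            synthetic_results(geom, axis_offset=(0.3, 0.0, 0.4)))
        assert wl_summary(wl)["magnitude_3d_mm"] == pytest.approx(0.5, abs=1e-6)

    def test_magnitude_invariant_under_axis_permutation(self, geom):
        for offset in ((0.3, 0.0, 0.4), (0.4, 0.3, 0.0), (0.0, 0.4, 0.3)):
            wl = fit_radiation_isocenter(synthetic_results(geom, axis_offset=offset))
            assert wl_summary(wl)["magnitude_3d_mm"] == pytest.approx(0.5, abs=1e-6)


class TestEndToEndRecovery:
    def test_rendered_session_recovery(self, phantom, geom, rng):
        # rendered (not synthetic-result) loop at moderate replication:
        # radiation offsets and BB offsets up to 1 mm, noise-free
        for _ in range(5):
            iso = rng.uniform(-1, 1, 3)
            bb = rng.uniform(-1, 1, 3)
            results = []
            for cp in build_sequence("winston_lutz").control_points:
                g = geom.replace(gantry_deg=cp.gantry_deg,
                                 collimator_deg=cp.collimator_deg,
                                 couch_deg=cp.couch_deg)
                a = np.radians(cp.couch_deg)
                rot = np.array([[np.cos(a), -np.sin(a), 0],
                                [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
                u_ax, v_ax, _ = imager_axes(g)
                shift = np.array([iso @ u_ax, iso @ v_ax])
                img = render_planar(phantom, (rot, rot @ bb), g, WL_FIELD,
                                    field_shift_iso=shift)
                results.append(wl_image_deviation(img, phantom))
            wl = fit_radiation_isocenter(results)
            assert np.all(np.abs(wl.phantom_shift - (iso - bb)) < 0.1)
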