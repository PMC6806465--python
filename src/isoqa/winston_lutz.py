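"""Winston-Lutz analysis: per-image field-vs-BB deviations, the 3D
radiation isocenter, and rotational walkout metrics.

Each of the twelve ball-and-field images yields the 2D deviation of the
radiation-field center from the central-BB centroid at the isocenter plane
(deviation = field - BB, so a positive deviation puts the field on the
positive-axis side of the phantom).  Every field center back-projects to a
central-axis ray; the radiation isocenter is the least-squares point
minimizing the summed squared perpendicular distances to all rays.

Walkout for each rotation axis is the maximum point-to-ray distance of the
fitted isocenter within that axis's image subgroup (the shared reference
image at gantry/collimator/couch = 0 belongs to all three subgroups).  A
diameter-style definition (max pairwise ray distance) can be selected via
``walkout_mode="diameter"``.

Couch-rotated images physically move the BB, so the BB's 3D position is
triangulated from the couch-0 gantry-sweep images only; couch-image
deviations inform the couch walkout, never the BB position.  The phantom
shift is the radiation isocenter relative to the OSMS/BB position
(radiation_isocenter - bb_position) per the package sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DetectionError, UnderdeterminedError
from .geometry import BeamGeometry, Ray3D, imager_to_iso_plane, ray_through_imager_point
from .images import PlanarImage
from .phantom import PhantomSpec, default_phantom
from .pose import ProjectionObservation, triangulate_point
from .segmentation import contour_components, field_region, filter_by_area

__all__ = ["WLImageResult", "WLResult", "wl_image_deviation",
           "fit_radiation_isocenter", "wl_summary"]


@dataclass
class WLImageResult:
    """Field-vs-BB measurement of one ball-and-field image (iso-plane mm)."""

    geom: BeamGeometry
    field_center_iso: np.ndarray
    bb_center_iso: np.ndarray
    deviation_2d: np.ndarray = None
    deviation_norm_mm: float = None

    def __post_init__(self) -> None:
        self.field_center_iso = np.asarray(self.field_center_iso, dtype=float)
        self.bb_center_iso = np.asarray(self.bb_center_iso, dtype=float)
        if self.deviation_2d is None:
            self.deviation_2d = self.field_center_iso - self.bb_center_iso
        self.deviation_2d = np.asarray(self.deviation_2d, dtype=float)
        if self.deviation_norm_mm is None:
            self.deviation_norm_mm = float(np.linalg.norm(self.deviation_2d))

    def field_ray(self) -> Ray3D:
        """Back-projected central-axis ray through the measured field center."""
        mag = self.geom.magnification
        return ray_through_imager_point(self.field_center_iso * mag, self.geom)

    def to_dict(self) -> dict:
        return {"gantry_deg": self.geom.gantry_deg,
                "collimator_deg": self.geom.collimator_deg,
                "couch_deg": self.geom.couch_deg,
                "field_center_iso_mm": list(self.field_center_iso),
                "bb_center_iso_mm": list(self.bb_center_iso),
                "deviation_2d_mm": list(self.deviation_2d),
                "deviation_norm_mm": self.deviation_norm_mm}


@dataclass
class WLResult:
    """Radiation-isocenter determination from a full ball-and-field series."""

    radiation_isocenter: np.ndarray     # room mm (LAT, LNG, VRT)
    bb_position: np.ndarray             # room mm
    phantom_shift: np.ndarray           # radiation_isocenter - bb_position
    gantry_walkout_mm: float | None
    collimator_walkout_mm: float | None
    couch_walkout_mm: float | None
    fit_residual_rms_mm: float = 0.0
    per_image: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"radiation_isocenter_mm": list(self.radiation_isocenter),
                "bb_position_mm": list(self.bb_position),
                "phantom_shift_mm": list(self.phantom_shift),
                "gantry_walkout_mm": self.gantry_walkout_mm,
                "collimator_walkout_mm": self.collimator_walkout_mm,
                "couch_walkout_mm": self.couch_walkout_mm,
                "fit_residual_rms_mm": self.fit_residual_rms_mm,
                "per_image": [r.to_dict() for r in self.per_image]}


def wl_image_deviation(image: PlanarImage, phantom: PhantomSpec | None = None,
                       threshold_fraction: float = 0.5) -> WLImageResult:
    """Measure field center and central-BB centroid on one image.

    Both are demagnified to the isocenter plane; deviation = field - BB.
    The small ball-and-field aperture shows only the central BB; the single
    size-filtered dark region inside the field is taken as the BB.
    """
    phantom = phantom or default_phantom()
    geom = image.geom
    fm = field_region(image)
    regions = contour_components(image, threshold_fraction=threshold_fraction)
    r_px = (phantom.diameters()["central"] / 2.0
            * geom.magnification / geom.pixel_pitch_mm)
    regions = filter_by_area(regions, np.pi * r_px**2)
    half_diag = np.hypot(fm.width_mm, fm.height_mm) / 2.0
    inside = [r for r in regions
              if np.linalg.norm(r.centroid - fm.center) < half_diag]
    if not inside:
        raise DetectionError(
            f"no BB found inside the field (gantry {geom.gantry_deg:g})")
    bb = min(inside, key=lambda r: np.linalg.norm(r.centroid - fm.center))
    return WLImageResult(
        geom=geom,
        field_center_iso=imager_to_iso_plane(fm.center, geom),
        bb_center_iso=imager_to_iso_plane(bb.centroid, geom))


def _subgroup_walkout(iso: np.ndarray, results: list[WLImageResult],
                      mode: str) -> float | None:
    if not results:
        return None
    rays = [r.field_ray() for r in results]
    if mode == "diameter":
        if len(rays) < 2:
            return 0.0
        # max over pairs of the distance between closest points of two rays
        worst = 0.0
        for i, a in enumerate(rays):
            for b in rays[i + 1:]:
                n = np.cross(a.direction, b.direction)
                dn = np.linalg.norm(n)
                w = b.origin - a.origin
                if dn < 1e-12:
                    d = np.linalg.norm(np.cross(w, a.direction))
                else:
                    d = abs(w @ n) / dn
                worst = max(worst, float(d))
        return worst
    return max(r.distance_to(iso) for r in rays)


def fit_radiation_isocenter(results: list[WLImageResult],
                            walkout_mode: str = "max") -> WLResult:
    """Determine the radiation isocenter from a ball-and-field series.

    Requires >= 4 images spanning >= 3 distinct gantry angles for 3D
    determinacy.  The BB 3D position comes from the couch-0 gantry-sweep
    images; walkouts are evaluated per rotation-axis subgroup.
    """
    results = list(results)
    gantries = {round(r.geom.gantry_deg, 6) for r in results}
    if len(results) < 4 or len(gantries) < 3:
        raise UnderdeterminedError(
            "need >= 4 images over >= 3 distinct gantry angles")

    rays = [r.field_ray() for r in results]
    a_mat = np.zeros((3, 3))
    b_vec = np.zeros(3)
    for ray in rays:
        proj = np.eye(3) - np.outer(ray.direction, ray.direction)
        a_mat += proj
        b_vec += proj @ ray.origin
    iso = np.linalg.solve(a_mat, b_vec)
    rms = float(np.sqrt(np.mean([r.distance_to(iso) ** 2 for r in rays])))

    def is0(x):
        return abs(x % 360.0) < 1e-9

    gantry_group = [r for r in results
                    if is0(r.geom.couch_deg) and is0(r.geom.collimator_deg)]
    coll_group = [r for r in results
                  if is0(r.geom.gantry_deg) and is0(r.geom.couch_deg)]
    couch_group = [r for r in results
                   if is0(r.geom.gantry_deg) and is0(r.geom.collimator_deg)]

    obs = [ProjectionObservation(label="central",
                                 imager_point=r.bb_center_iso * r.geom.magnification,
                                 geom=r.geom)
           for r in gantry_group]
    bb_pos, _ = triangulate_point(obs)

    phantom_shift = iso - bb_pos
    return WLResult(
        radiation_isocenter=iso, bb_position=bb_pos,
        phantom_shift=phantom_shift,
        gantry_walkout_mm=_subgroup_walkout(iso, gantry_group, walkout_mode),
        collimator_walkout_mm=_subgroup_walkout(iso, coll_group, walkout_mode),
        couch_walkout_mm=_subgroup_walkout(iso, couch_group, walkout_mode),
        fit_residual_rms_mm=rms, per_image=results)


def wl_summary(result: WLResult) -> dict:
    """Scalar report: 3D magnitude of the phantom shift plus per-axis values."""
    shift = np.asarray(result.phantom_shift, dtype=float)
    return {"magnitude_3d_mm": float(np.linalg.norm(shift)),
            "lat_mm": float(shift[0]), "lng_mm": float(shift[1]),
            "vrt_mm": float(shift[2]),
            "gantry_walkout_mm": result.gantry_walkout_mm,
            "collimator_walkout_mm": result.collimator_walkout_mm,
            "couch_walkout_mm": result.couch_walkout_mm}
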