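"""6D isocenter-shift estimation from matched BB observations.

Two routes feed the same rigid estimator:

* planar (MV / kV): BBs detected in the four cardinal-gantry images are
  back-projected to source rays and triangulated per label across angles,
  then the triangulated set is rigidly fit to the nominal phantom layout;
* volumetric (CBCT vs CT): BB centroids from both volumes are rigidly fit
  to each other.

The rigid fit is a least-squares superposition (centroid alignment +
SVD orthogonal decomposition with the proper-rotation constraint).  The
fitted pose maps nominal -> measured, i.e. it is the apparent phantom pose
in the tested system's frame; the reported isocenter shift is its inverse,
following the package sign convention (positive shift = tested system's
isocenter on the positive-axis side of the phantom position).  Couch-style
correction vectors from volume registration are thereby negated into the
same convention.

Single joint fit vs per-angle merging: triangulating every label across
all four angles and solving one rigid problem is a single well-posed
least-squares estimate; per-image matched centroids remain available as
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConditioningError,
    DegenerateConfigurationError,
    DetectionError,
    UnderdeterminedError,
)
from .geometry import BeamGeometry, Pose6D, invert_pose, project_to_imager, ray_through_imager_point
from .images import PlanarImage, VolumeImage
from .phantom import PhantomSpec
from .segmentation import bb_centroids_3d, contour_components, filter_by_area, match_bbs

__all__ = ["ProjectionObservation", "ShiftResult", "triangulate_point",
           "rigid_fit", "planar_isocenter_shift", "register_cbct_to_ct"]

#: Rays closer to parallel than this (line-angle, degrees) cannot triangulate.
MIN_ANGLE_SEP_DEG = 10.0
#: Normal-matrix condition number above which triangulation is rejected.
MAX_CONDITION = 1e8


@dataclass(frozen=True)
class ProjectionObservation:
    """One BB seen on one imager: label, imager-plane point (mm), geometry."""

    label: str
    imager_point: np.ndarray
    geom: BeamGeometry

    def __post_init__(self) -> None:
        p = np.asarray(self.imager_point, dtype=float).reshape(2)
        object.__setattr__(self, "imager_point", p)
        half_u = self.geom.imager_cols * self.geom.pixel_pitch_mm / 2.0
        half_v = self.geom.imager_rows * self.geom.pixel_pitch_mm / 2.0
        if abs(p[0]) > half_u or abs(p[1]) > half_v:
            raise DetectionError(
                f"observation of {self.label!r} outside imager bounds")


@dataclass
class ShiftResult:
    """A 6D isocenter shift with its fit residual and provenance."""

    pose: Pose6D
    residual_rms_mm: float
    n_observations: int
    quality_warning: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_rms_mm < 0:
            raise ValueError("residual must be >= 0")

    def to_dict(self) -> dict:
        return {"pose": self.pose.to_dict(),
                "residual_rms_mm": self.residual_rms_mm,
                "n_observations": self.n_observations,
                "quality_warning": self.quality_warning}


def _line_angle_deg(d1: np.ndarray, d2: np.ndarray) -> float:
    """Angle between two lines (directions mod sign), in degrees."""
    c = abs(float(np.clip(d1 @ d2, -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


def triangulate_point(observations) -> tuple[np.ndarray, float]:
    """Least-squares 3D point from >= 2 back-projected rays.

    Minimizes the sum of squared perpendicular distances to the rays from
    the source through each imager point.  Returns ``(point, residual_rms)``
    in room mm.

    Raises
    ------
    UnderdeterminedError
        Fewer than two observations.
    ConditioningError
        All ray pairs closer to parallel than 10 deg, or an
        ill-conditioned normal matrix.
    """
    observations = list(observations)
    if len(observations) < 2:
        raise UnderdeterminedError("triangulation needs >= 2 observations")
    rays = [ray_through_imager_point(o.imager_point, o.geom) for o in observations]
    max_sep = max(_line_angle_deg(a.direction, b.direction)
                  for i, a in enumerate(rays) for b in rays[i + 1:])
    if max_sep < MIN_ANGLE_SEP_DEG:
        raise ConditioningError(
            f"rays separated by at most {max_sep:.2f} deg (< {MIN_ANGLE_SEP_DEG})")

    a_mat = np.zeros((3, 3))
    b_vec = np.zeros(3)
    for ray in rays:
        proj = np.eye(3) - np.outer(ray.direction, ray.direction)
        a_mat += proj
        b_vec += proj @ ray.origin
    if np.linalg.cond(a_mat) > MAX_CONDITION:
        raise ConditioningError("near-parallel rays: normal matrix ill-conditioned")
    point = np.linalg.solve(a_mat, b_vec)
    residual = float(np.sqrt(np.mean([r.distance_to(point) ** 2 for r in rays])))
    return point, residual


def rigid_fit(measured, nominal) -> ShiftResult:
    """Least-squares rigid superposition of labeled point sets.

    ``measured``/``nominal`` are sequences of ``(label, 3-vector)`` sharing
    labels.  Finds the proper rotation R and translation t minimizing
    ``sum |R n_i + t - m_i|^2`` (centroid alignment + SVD with the
    det(R) = +1 constraint, so reflections are never returned) and
    decomposes the result into VRT/LNG/LAT/pitch/roll/Rtn.
    """
    meas = {lab: np.asarray(p, dtype=float) for lab, p in measured}
    nom = {lab: np.asarray(p, dtype=float) for lab, p in nominal}
    labels = [lab for lab in nom if lab in meas]
    if len(labels) < 3:
        raise UnderdeterminedError("rigid fit needs >= 3 point pairs")
    m = np.array([meas[lab] for lab in labels])
    n = np.array([nom[lab] for lab in labels])

    mc, nc = m.mean(axis=0), n.mean(axis=0)
    m0, n0 = m - mc, n - nc
    sv = np.linalg.svd(n0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError(
            "nominal points collinear or coincident: rotation undetermined")
    h = n0.T @ m0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mc - rot @ nc
    res = m - (n @ rot.T + t)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return ShiftResult(pose=Pose6D.from_rt(rot, t), residual_rms_mm=rms,
                       n_observations=len(labels))


def detect_bb_observations(image: PlanarImage, phantom: PhantomSpec,
                           threshold_fraction: float = 0.5,
                           gate_mm: float = 5.0) -> list[ProjectionObservation]:
    """Detect and label all phantom BBs on one planar image.

    Predictions for label matching are the divergent projections of the
    nominal (unshifted) BB positions — valid while true shifts stay well
    inside the matching gate, which holds with a wide margin in the QA
    regime.  ``gate_mm`` is stated at the isocenter plane and scaled by the
    imaging magnification before matching on the imager.  Size-filters
    candidate regions against the projected BB disc area before matching.
    """
    geom = image.geom
    regions = contour_components(image, threshold_fraction=threshold_fraction)
    r_px = (np.mean([b[2] for b in phantom.bbs]) / 2.0
            * geom.magnification / geom.pixel_pitch_mm)
    regions = filter_by_area(regions, np.pi * r_px**2)
    expected = [(lab, project_to_imager(pos, geom))
                for lab, pos in phantom.positions().items()]
    try:
        labeled = match_bbs(regions, expected,
                            gate_mm=gate_mm * geom.magnification)
    except DetectionError as exc:
        raise DetectionError(
            f"gantry {geom.gantry_deg:g} deg: {exc}") from exc
    return [ProjectionObservation(label=r.label, imager_point=r.centroid,
                                  geom=geom) for r in labeled]


def planar_isocenter_shift(images, phantom: PhantomSpec,
                           threshold_fraction: float = 0.5) -> ShiftResult:
    """Full planar pipeline: detect -> match -> triangulate -> rigid fit.

    ``images`` are the (typically four) cardinal-gantry-angle views of one
    modality.  Every BB must be detectable in every image.  The returned
    pose is the modality's isocenter shift relative to the phantom (OSMS)
    position in the package sign convention.
    """
    images = list(images)
    obs_by_label: dict[str, list[ProjectionObservation]] = {}
    for img in images:
        for obs in detect_bb_observations(img, phantom,
                                          threshold_fraction=threshold_fraction):
            obs_by_label.setdefault(obs.label, []).append(obs)

    measured = []
    tri_residuals = {}
    for lab, obs in obs_by_label.items():
        try:
            point, resid = triangulate_point(obs)
        except (UnderdeterminedError, ConditioningError) as exc:
            angles = [o.geom.gantry_deg for o in obs]
            raise type(exc)(f"BB {lab!r} at gantry angles {angles}: {exc}") from exc
        measured.append((lab, point))
        tri_residuals[lab] = resid

    fit = rigid_fit(measured, list(phantom.positions().items()))
    shift = invert_pose(fit.pose)
    return ShiftResult(pose=shift, residual_rms_mm=fit.residual_rms_mm,
                       n_observations=sum(len(v) for v in obs_by_label.values()),
                       diagnostics={"triangulation_residual_mm": tri_residuals,
                                    "apparent_phantom_pose": fit.pose.to_dict()})


def register_cbct_to_ct(cbct: VolumeImage, ct: VolumeImage,
                        phantom: PhantomSpec,
                        residual_warn_mm: float = 1.0) -> ShiftResult:
    """BB-centroid rigid registration of a CBCT volume onto the CT.

    The phantom's information content is its BBs, so the registration uses
    their centroids rather than grey values (stands in for a
    phantom-priority online match).  Reported as the CBCT-isocenter
    displacement under the sign convention; an RMS residual above
    ``residual_warn_mm`` sets the quality flag.
    """
    nominal = list(phantom.positions().items())
    diam = float(np.mean([b[2] for b in phantom.bbs]))
    ct_pts = bb_centroids_3d(ct, nominal, bb_diameter_mm=diam)
    cbct_pts = bb_centroids_3d(cbct, nominal, bb_diameter_mm=diam)
    fit = rigid_fit([(r.label, r.centroid) for r in cbct_pts],
                    [(r.label, r.centroid) for r in ct_pts])
    shift = invert_pose(fit.pose)
    return ShiftResult(pose=shift, residual_rms_mm=fit.residual_rms_mm,
                       n_observations=fit.n_observations,
                       quality_warning=fit.residual_rms_mm > residual_warn_mm,
                       diagnostics={"apparent_phantom_pose": fit.pose.to_dict()})
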