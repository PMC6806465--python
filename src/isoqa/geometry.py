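"""Coordinate frames, rigid 6D poses and the divergent projection model.

Room frame (IEC 61217-like, fixed for the whole package):

* ``+X`` = LAT (lateral, toward the patient's left at head-first supine),
* ``+Y`` = LNG (longitudinal, toward the gantry),
* ``+Z`` = VRT (vertical, up).

The gantry rotates about ``+Y``; the couch rotates about ``+Z``; the
collimator rotates about the beam axis.  At gantry 0 the source sits
vertically above the isocenter at ``(0, 0, +SAD)`` and the beam points
straight down.

A 6D pose is the translation ``(LAT, LNG, VRT)`` in mm plus the rotations
pitch (about LAT), roll (about LNG) and Rtn (about VRT) in degrees, composed
as ``R = Rz(rtn) @ Rx(pitch) @ Ry(roll)`` (roll applied first).  The QA
regime only ever sees sub-degree rotations, where alternative composition
orders agree to well below measurement precision, but one order must be
fixed for exact round-trips.

Sign convention for reported shifts: a positive shift means the tested
system's isocenter lies on the positive-axis side of the surface-imaging
(phantom) setup position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError

__all__ = [
    "Pose6D",
    "BeamGeometry",
    "Ray3D",
    "rotation_from_angles",
    "angles_from_rotation",
    "apply_pose",
    "invert_pose",
    "compose_poses",
    "source_position",
    "imager_axes",
    "beam_ray",
    "project_to_imager",
    "imager_to_iso_plane",
]

#: Rotations beyond this magnitude are outside the QA regime and rejected.
MAX_ROTATION_DEG = 45.0


@dataclass(frozen=True)
class Pose6D:
    """Rigid 6D pose: translations in mm, rotations in degrees.

    ``vrt_mm``/``lng_mm``/``lat_mm`` are signed translations along the room
    VRT/LNG/LAT axes; ``pitch_deg``/``roll_deg``/``rtn_deg`` are signed
    rotations about LAT/LNG/VRT.
    """

    vrt_mm: float = 0.0
    lng_mm: float = 0.0
    lat_mm: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    rtn_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("vrt_mm", "lng_mm", "lat_mm",
                     "pitch_deg", "roll_deg", "rtn_deg"):
            object.__setattr__(self, name, float(getattr(self, name)))
        vals = (self.vrt_mm, self.lng_mm, self.lat_mm,
                self.pitch_deg, self.roll_deg, self.rtn_deg)
        if not all(math.isfinite(v) for v in vals):
            raise DomainError(f"pose fields must be finite, got {vals}")
        for name in ("pitch_deg", "roll_deg", "rtn_deg"):
            if abs(getattr(self, name)) >= MAX_ROTATION_DEG:
                raise DomainError(
                    f"{name}={getattr(self, name)} outside the QA regime "
                    f"(|rotation| < {MAX_ROTATION_DEG} deg)")

    @property
    def translation(self) -> np.ndarray:
        """Translation vector in room-axis order ``(LAT, LNG, VRT)`` [mm]."""
        return np.array([self.lat_mm, self.lng_mm, self.vrt_mm])

    @property
    def rotation(self) -> np.ndarray:
        """3x3 proper rotation matrix of this pose."""
        return rotation_from_angles(self.pitch_deg, self.roll_deg, self.rtn_deg)

    def as_array(self) -> np.ndarray:
        """Six components as ``(vrt, lng, lat, pitch, roll, rtn)``."""
        return np.array([self.vrt_mm, self.lng_mm, self.lat_mm,
                         self.pitch_deg, self.roll_deg, self.rtn_deg])

    @classmethod
    def from_rt(cls, rotation: np.ndarray, translation: np.ndarray) -> "Pose6D":
        """Build a pose from a rotation matrix and a (LAT, LNG, VRT) translation."""
        pitch, roll, rtn = angles_from_rotation(rotation)
        lat, lng, vrt = np.asarray(translation, dtype=float)
        return cls(vrt_mm=vrt, lng_mm=lng, lat_mm=lat,
                   pitch_deg=pitch, roll_deg=roll, rtn_deg=rtn)

    def to_dict(self) -> dict:
        return {"vrt_mm": self.vrt_mm, "lng_mm": self.lng_mm,
                "lat_mm": self.lat_mm, "pitch_deg": self.pitch_deg,
                "roll_deg": self.roll_deg, "rtn_deg": self.rtn_deg}


@dataclass(frozen=True)
class BeamGeometry:
    """Beam/imager geometry for one acquisition.

    Angles are accepted in degrees and normalized to ``[0, 360)``.
    ``sad_mm`` is the source-to-isocenter distance, ``sid_mm`` the
    source-to-imager distance; their ratio is the imaging magnification.
    """

    gantry_deg: float = 0.0
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    sad_mm: float = 1000.0
    sid_mm: float = 1500.0
    pixel_pitch_mm: float = 0.336
    imager_rows: int = 1024
    imager_cols: int = 1024

    def __post_init__(self) -> None:
        if not (self.sid_mm > self.sad_mm > 0):
            raise DomainError(
                f"require sid_mm > sad_mm > 0, got sid={self.sid_mm}, sad={self.sad_mm}")
        if self.pixel_pitch_mm <= 0:
            raise DomainError("pixel_pitch_mm must be positive")
        if self.imager_rows <= 0 or self.imager_cols <= 0:
            raise DomainError("imager dimensions must be positive")
        for name in ("gantry_deg", "collimator_deg", "couch_deg"):
            v = float(getattr(self, name)) % 360.0
            object.__setattr__(self, name, v)

    @property
    def magnification(self) -> float:
        return self.sid_mm / self.sad_mm

    def replace(self, **kw) -> "BeamGeometry":
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d.update(kw)
        return BeamGeometry(**d)

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


@dataclass(frozen=True)
class Ray3D:
    """A ray in the room frame: ``origin`` in mm, unit ``direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            raise DomainError(f"ray direction must be unit norm, |d|={n}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction

    def distance_to(self, point: np.ndarray) -> float:
        """Perpendicular distance from a point to the (infinite) ray line."""
        w = np.asarray(point, dtype=float) - self.origin
        return float(np.linalg.norm(w - (w @ self.direction) * self.direction))


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_from_angles(pitch_deg: float, roll_deg: float,
                         rtn_deg: float) -> np.ndarray:
    """Rotation matrix ``Rz(rtn) @ Rx(pitch) @ Ry(roll)``.

    Pitch is about LAT (+X), roll about LNG (+Y), Rtn about VRT (+Z);
    roll is applied first, then pitch, then Rtn.

    Raises
    ------
    DomainError
        If any angle magnitude is >= 45 deg (outside the QA regime).
    """
    for name, v in (("pitch", pitch_deg), ("roll", roll_deg), ("rtn", rtn_deg)):
        if not math.isfinite(v) or abs(v) >= MAX_ROTATION_DEG:
            raise DomainError(f"{name}={v} outside |angle| < {MAX_ROTATION_DEG} deg")
    p, r, t = (math.radians(pitch_deg), math.radians(roll_deg),
               math.radians(rtn_deg))
    return _rz(t) @ _rx(p) @ _ry(r)


def angles_from_rotation(rot: np.ndarray) -> tuple[float, float, float]:
    """Recover ``(pitch, roll, rtn)`` in degrees from a rotation matrix.

    Inverse of :func:`rotation_from_angles`; unique in the QA regime
    (|pitch| < 90 deg, so cos(pitch) > 0).
    """
    rot = np.asarray(rot, dtype=float)
    pitch = math.asin(np.clip(rot[2, 1], -1.0, 1.0))
    roll = math.atan2(-rot[2, 0], rot[2, 2])
    rtn = math.atan2(-rot[0, 1], rot[1, 1])
    return math.degrees(pitch), math.degrees(roll), math.degrees(rtn)


def apply_pose(pose: Pose6D, point: np.ndarray) -> np.ndarray:
    """Apply ``R @ point + t`` with t = (LAT, LNG, VRT) on room axes.

    ``point`` may be a single 3-vector or an (N, 3) stack.
    """
    p = np.asarray(point, dtype=float)
    return p @ pose.rotation.T + pose.translation


def invert_pose(pose: Pose6D) -> Pose6D:
    """Exact rigid inverse: ``R' = R.T``, ``t' = -R.T @ t``."""
    rt = pose.rotation.T
    return Pose6D.from_rt(rt, -rt @ pose.translation)


def compose_poses(outer: Pose6D, inner: Pose6D) -> Pose6D:
    """Pose equivalent to applying ``inner`` first, then ``outer``."""
    r = outer.rotation @ inner.rotation
    t = outer.rotation @ inner.translation + outer.translation
    return Pose6D.from_rt(r, t)


def source_position(geom: BeamGeometry) -> np.ndarray:
    """Source location for the geometry's gantry angle (room frame, mm)."""
    g = math.radians(geom.gantry_deg)
    return _ry(g) @ np.array([0.0, 0.0, geom.sad_mm])


def imager_axes(geom: BeamGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors ``(u, v, w)`` of the imager for this gantry angle.

    ``u`` is the gantry-rotated +X direction, ``v`` is +Y (LNG), and ``w``
    is the beam direction (source toward isocenter).  The collimator angle
    rotates the *field*, not the imager, so it does not enter here.
    """
    g = math.radians(geom.gantry_deg)
    rot = _ry(g)
    u = rot @ np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    w = rot @ np.array([0.0, 0.0, -1.0])
    return u, v, w


def beam_ray(geom: BeamGeometry) -> Ray3D:
    """Central-axis ray: origin at the source, direction source -> isocenter."""
    src = source_position(geom)
    return Ray3D(origin=src, direction=-src / np.linalg.norm(src))


def project_to_imager(point: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Central (divergent) projection of a room point onto the imager [mm].

    The imager plane is perpendicular to the beam axis at ``sid_mm`` from
    the source; a point at the isocenter maps to (0, 0) for every gantry
    angle.  Accepts a 3-vector or an (N, 3) stack.
    """
    u, v, w = imager_axes(geom)
    src = source_position(geom)
    p = np.asarray(point, dtype=float)
    rel = p - src
    depth = rel @ w
    if np.any(depth <= 0):
        raise GeometryError("point at or behind the source cannot be projected")
    if np.any(depth >= geom.sid_mm):
        raise GeometryError("point not on the source side of the imager plane")
    scale = geom.sid_mm / depth
    out = np.stack([(rel @ u) * scale, (rel @ v) * scale], axis=-1)
    return out


def imager_to_iso_plane(p: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Demagnify imager-plane mm coordinates to the isocenter plane."""
    return np.asarray(p, dtype=float) * (geom.sad_mm / geom.sid_mm)


def ray_through_imager_point(p: np.ndarray, geom: BeamGeometry) -> Ray3D:
    """Back-project an imager-plane point (mm) to its source ray."""
    u, v, w = imager_axes(geom)
    src = source_position(geom)
    p = np.asarray(p, dtype=float)
    target = src + geom.sid_mm * w + p[0] * u + p[1] * v
    d = target - src
    return Ray3D(origin=src, direction=d / np.linalg.norm(d))
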