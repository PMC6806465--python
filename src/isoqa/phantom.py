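"""Five-BB cube phantom model and the seeded synthetic image renderer.

The phantom is a 15 cm plastic cube holding five 7.5 mm alumina-ceramic
ball bearings (BBs): one at the cube center and four placed asymmetrically
off-center, the furthest 45 mm from the center.  The asymmetric layout is
what makes a full 6D pose recoverable from projections — no two BBs share
any coordinate, so no reflection or rotation of the set is self-similar.

The renderer produces every image the analysis pipeline consumes:

* :func:`render_planar` — a divergent-beam transmission radiograph: an
  open rectangular field (Gaussian-smoothed penumbra) attenuated by exact
  line integrals through the cube and the spherical BBs at their posed,
  projected positions, plus seeded additive Gaussian noise.  Open field is
  bright (level 1.0), attenuated regions dark.
* :func:`render_volume` — a voxelized cube with spherical BB inclusions,
  linear partial-volume weighting at material surfaces (stands in for the
  reconstructed CT / CBCT volume; no projection-reconstruction chain is
  simulated because only the reconstructed volume is analyzed).
* :func:`simulate_session` — one full weekly QA session: CT, CBCT, four
  cardinal-angle MV + kV pairs and the 12-image Winston-Lutz set, with the
  per-modality ground truth retained.

Material values are relative linear attenuation per mm; volumes store the
same numbers as voxel intensities, so BB > plastic > background ordering
holds in both domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .errors import DomainError, GeometryError
from .geometry import (
    BeamGeometry,
    Pose6D,
    imager_axes,
    imager_to_iso_plane,
    invert_pose,
    project_to_imager,
    source_position,
)
from .images import PlanarImage, VolumeImage

__all__ = [
    "PhantomSpec",
    "FieldAperture",
    "SessionTruth",
    "SessionDataset",
    "default_phantom",
    "render_planar",
    "render_volume",
    "simulate_session",
    "MV_FIELD",
    "KV_FIELD",
    "WL_FIELD",
]

#: Default additive planar noise sigma as a fraction of the open-field level.
DEFAULT_PLANAR_NOISE = 0.01
#: Default volume noise sigma as a fraction of the BB-background contrast.
DEFAULT_VOLUME_NOISE_FRACTION = 0.02

#: Acquisition field apertures (sizes defined at the isocenter plane, mm).
MV_FIELD_MM = 100.0
KV_FIELD_MM = 110.0
WL_FIELD_MM = 25.0


@dataclass(frozen=True)
class FieldAperture:
    """Rectangular field aperture defined at the isocenter plane."""

    width_mm: float
    height_mm: float
    penumbra_sigma_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise DomainError("field width/height must be positive")
        if self.penumbra_sigma_mm < 0:
            raise DomainError("penumbra sigma must be >= 0")


MV_FIELD = FieldAperture(MV_FIELD_MM, MV_FIELD_MM)
KV_FIELD = FieldAperture(KV_FIELD_MM, KV_FIELD_MM)
WL_FIELD = FieldAperture(WL_FIELD_MM, WL_FIELD_MM)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material contrasts of the multi-BB cube phantom.

    ``bbs`` maps label -> (3-vector position in the phantom frame [mm],
    diameter [mm]).  Exactly one BB labeled ``central`` must sit at the
    origin.  Intensities are relative attenuation per mm.
    """

    bbs: tuple = ()
    cube_side_mm: float = 150.0
    bb_intensity: float = 0.070
    plastic_intensity: float = 0.0015
    background_intensity: float = 0.0

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.bbs]
        if len(set(labels)) != len(labels):
            raise DomainError("duplicate BB labels")
        central = [b for b in self.bbs if b[0] == "central"]
        if len(central) != 1 or np.linalg.norm(central[0][1]) != 0.0:
            raise DomainError("exactly one BB labeled 'central' at (0,0,0) required")
        half = self.cube_side_mm / 2.0
        for label, pos, diam in self.bbs:
            pos = np.asarray(pos, dtype=float)
            if np.any(np.abs(pos) + diam / 2.0 > half):
                raise DomainError(f"BB {label!r} extends outside the cube")
        for i, (la, pa, da) in enumerate(self.bbs):
            for lb, pb, db in self.bbs[i + 1:]:
                sep = np.linalg.norm(np.asarray(pa, float) - np.asarray(pb, float))
                if sep <= (da + db) / 2.0:
                    raise DomainError(f"BBs {la!r} and {lb!r} overlap")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bbs]

    def positions(self) -> dict[str, np.ndarray]:
        return {b[0]: np.asarray(b[1], dtype=float) for b in self.bbs}

    def diameters(self) -> dict[str, float]:
        return {b[0]: float(b[2]) for b in self.bbs}


def default_phantom() -> PhantomSpec:
    """The stock five-BB cube: 15 cm side, 7.5 mm BBs, max offset 45 mm.

    The four off-center BBs occupy four distinct octants at 28–45 mm from
    the center and share no coordinate value on any axis, so the layout has
    no symmetry a projection could confuse.  The exact off-center
    coordinates are a configurable package choice (only the count, BB
    diameter and the 45 mm maximum are fixed properties of the physical
    phantom).
    """
    d = 7.5
    return PhantomSpec(bbs=(
        ("central", (0.0, 0.0, 0.0), d),
        ("a1", (20.0, 12.0, -16.0), d),     # |r| = 28.3 mm
        ("a2", (-24.0, -18.0, 10.0), d),    # |r| = 31.6 mm
        ("a3", (14.0, -26.0, 22.0), d),     # |r| = 36.8 mm
        ("a4", (-20.0, 35.0, 20.0), d),     # |r| = 45.0 mm (furthest)
    ))


# ---------------------------------------------------------------------------
# planar rendering
# ---------------------------------------------------------------------------

def _pose_rt(pose) -> tuple[np.ndarray, np.ndarray]:
    """Accept a Pose6D or an explicit (R, t) pair (t on LAT/LNG/VRT axes)."""
    if isinstance(pose, Pose6D):
        return pose.rotation, pose.translation
    r, t = pose
    return np.asarray(r, dtype=float), np.asarray(t, dtype=float).reshape(3)


def _edge_profile(x: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Transmission of one pair of opposing field edges with Gaussian penumbra."""
    if sigma <= 0:
        return ((np.abs(x) <= half_width)).astype(float)
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((half_width - x) / s) + erf((half_width + x) / s))


def render_planar(phantom: PhantomSpec, pose, geom: BeamGeometry,
                  aperture: FieldAperture, field_shift_iso=(0.0, 0.0),
                  noise_sigma: float = 0.0, seed: int = 0) -> PlanarImage:
    """Render a transmission radiograph of the posed phantom.

    Parameters
    ----------
    pose
        Phantom pose in the imaging frame (Pose6D, or an explicit
        ``(R, t)`` pair for poses outside the Pose6D rotation range, e.g.
        couch-rotated Winston-Lutz views).
    field_shift_iso
        Displacement of the field center from the beam axis, given at the
        isocenter plane in imager (u, v) mm — used to emulate a radiation
        isocenter offset or per-image axis walkout.
    noise_sigma
        Additive Gaussian noise sigma in open-field units (open field = 1).
        Rendering is bit-deterministic for fixed arguments and seed.
    """
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    mag = geom.magnification
    pitch = geom.pixel_pitch_mm
    half_u = geom.imager_cols * pitch / 2.0
    half_v = geom.imager_rows * pitch / 2.0
    shift = np.asarray(field_shift_iso, dtype=float) * mag
    if (aperture.width_mm * mag / 2 + abs(shift[0]) > half_u
            or aperture.height_mm * mag / 2 + abs(shift[1]) > half_v):
        raise GeometryError("field aperture does not fit on the imager")

    img = PlanarImage(np.zeros((geom.imager_rows, geom.imager_cols)), geom)

    # the open field bounds everything visible: restrict the heavy ray math
    # to its bounding box (plus penumbra margin); outside it fluence ~ 0
    ca_r = math.radians(geom.collimator_deg)
    half_u_f = (abs(aperture.width_mm * math.cos(ca_r))
                + abs(aperture.height_mm * math.sin(ca_r))) * mag / 2.0
    half_v_f = (abs(aperture.width_mm * math.sin(ca_r))
                + abs(aperture.height_mm * math.cos(ca_r))) * mag / 2.0
    margin = 6.0 * max(sig_m := aperture.penumbra_sigma_mm * mag, 1.0)
    rc = img.mm_to_pixel(shift[0], shift[1])
    r_lo = max(0, int(math.floor(rc[0] - (half_v_f + margin) / pitch)))
    r_hi = min(geom.imager_rows, int(math.ceil(rc[0] + (half_v_f + margin) / pitch)) + 1)
    c_lo = max(0, int(math.floor(rc[1] - (half_u_f + margin) / pitch)))
    c_hi = min(geom.imager_cols, int(math.ceil(rc[1] + (half_u_f + margin) / pitch)) + 1)
    uv = img.pixel_to_mm(np.arange(r_lo, r_hi)[:, None],
                         np.arange(c_lo, c_hi)[None, :])
    u, v = uv[..., 0], uv[..., 1]

    # open-field fluence, collimator-rotated about the (shifted) field center
    ca = math.radians(geom.collimator_deg)
    cu, sv = u - shift[0], v - shift[1]
    uf = cu * math.cos(ca) + sv * math.sin(ca)
    vf = -cu * math.sin(ca) + sv * math.cos(ca)
    fluence = (_edge_profile(uf, aperture.width_mm * mag / 2.0, sig_m)
               * _edge_profile(vf, aperture.height_mm * mag / 2.0, sig_m))

    # per-pixel unit ray directions in the room frame
    u_ax, v_ax, w_ax = imager_axes(geom)
    src = source_position(geom)
    norm = np.sqrt(geom.sid_mm**2 + u**2 + v**2)
    d = np.stack([(geom.sid_mm * w_ax[k] + u * u_ax[k] + v * v_ax[k]) / norm
                  for k in range(3)])

    rot, trans = _pose_rt(pose)
    # rays in the phantom frame
    o_ph = rot.T @ (src - trans)
    d_ph = np.tensordot(rot.T, d, axes=1)

    # chord through the cube (slab method)
    half = phantom.cube_side_mm / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d_ph
        t1 = (-half - o_ph[:, None, None]) * inv
        t2 = (half - o_ph[:, None, None]) * inv
    tnear = np.max(np.minimum(t1, t2), axis=0)
    tfar = np.min(np.maximum(t1, t2), axis=0)
    cube_chord = np.clip(tfar - tnear, 0.0, None)

    # chords through each BB sphere
    bb_chord = np.zeros_like(cube_chord)
    for label, ppos, diam in phantom.bbs:
        c = rot @ np.asarray(ppos, dtype=float) + trans
        rel_c = c - src
        b = np.tensordot(rel_c, d, axes=1)
        h2 = float(rel_c @ rel_c) - b**2
        r2 = (diam / 2.0) ** 2
        bb_chord += 2.0 * np.sqrt(np.clip(r2 - h2, 0.0, None))

    mu_p = phantom.plastic_intensity
    mu_b = phantom.bb_intensity
    # BBs are embedded in the plastic: their chord replaces plastic path
    # (air outside the cube attenuates ~nothing and is not modeled)
    path = mu_p * (cube_chord - bb_chord) + mu_b * bb_chord
    pixels = np.zeros((geom.imager_rows, geom.imager_cols))
    pixels[r_lo:r_hi, c_lo:c_hi] = fluence * np.exp(-path)

    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        pixels = pixels + rng.normal(0.0, noise_sigma, size=pixels.shape)
    img.pixels = pixels
    img.meta = {"aperture_mm": [aperture.width_mm, aperture.height_mm],
                "field_shift_iso_mm": list(np.asarray(field_shift_iso, float)),
                "noise_sigma": noise_sigma, "seed": int(seed)}
    return img


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------

def render_volume(phantom: PhantomSpec, pose, voxel_mm: float,
                  noise_sigma: float = 0.0, seed: int = 0,
                  margin_mm: float = 8.0) -> VolumeImage:
    """Voxelize the posed phantom on an isotropic grid centered at the origin.

    Material boundaries get linear partial-volume weighting over one voxel,
    which keeps intensity-weighted BB centroids accurate to well under a
    tenth of a voxel.  Deterministic for fixed arguments and seed.
    """
    if voxel_mm <= 0:
        raise DomainError("voxel_mm must be positive")
    rot, trans = _pose_rt(pose)
    half = phantom.cube_side_mm / 2.0
    # bounding half-extent of the rotated, shifted cube
    corners = np.array([[sx, sy, sz] for sx in (-half, half)
                        for sy in (-half, half) for sz in (-half, half)])
    posed = corners @ rot.T + trans
    need = np.max(np.abs(posed)) + margin_mm
    n = int(math.ceil(2 * need / voxel_mm)) | 1  # odd => a voxel center at origin
    origin = -((n - 1) / 2.0) * voxel_mm * np.ones(3)
    extent = ((n - 1) / 2.0) * voxel_mm
    if np.max(np.abs(posed)) > extent:
        raise GeometryError("posed cube exceeds the volume extent")

    ax = (np.arange(n) * voxel_mm + origin[0]).astype(np.float32)
    x = ax[:, None, None]
    y = ax[None, :, None]
    z = ax[None, None, :]
    rt = rot.T.astype(np.float32)
    tx, ty, tz = trans.astype(np.float32)
    # phantom-frame coordinates of every voxel center
    px = rt[0, 0] * (x - tx) + rt[0, 1] * (y - ty) + rt[0, 2] * (z - tz)
    py = rt[1, 0] * (x - tx) + rt[1, 1] * (y - ty) + rt[1, 2] * (z - tz)
    pz = rt[2, 0] * (x - tx) + rt[2, 1] * (y - ty) + rt[2, 2] * (z - tz)

    cheb = np.maximum(np.maximum(np.abs(px), np.abs(py)), np.abs(pz))
    w_cube = np.clip((half + voxel_mm / 2.0 - cheb) / voxel_mm, 0.0, 1.0)
    vox = (phantom.background_intensity
           + (phantom.plastic_intensity - phantom.background_intensity) * w_cube)
    del px, py, pz, cheb, w_cube

    for label, ppos, diam in phantom.bbs:
        c = rot @ np.asarray(ppos, dtype=float) + trans
        r = diam / 2.0
        lo = np.maximum(0, np.floor((c - r - 2 * voxel_mm - origin) / voxel_mm)).astype(int)
        hi = np.minimum(n, np.ceil((c + r + 2 * voxel_mm - origin) / voxel_mm) + 1).astype(int)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        gx = ax[sl[0]][:, None, None]
        gy = ax[sl[1]][None, :, None]
        gz = ax[sl[2]][None, None, :]
        dist = np.sqrt((gx - c[0])**2 + (gy - c[1])**2 + (gz - c[2])**2)
        w_bb = np.clip((r + voxel_mm / 2.0 - dist) / voxel_mm, 0.0, 1.0)
        vox[sl] += (phantom.bb_intensity - phantom.plastic_intensity) * w_bb

    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        vox = vox + noise_sigma * rng.standard_normal(vox.shape, dtype=np.float32)
    return VolumeImage(voxels=vox, spacing=voxel_mm, origin=origin,
                       meta={"voxel_mm": voxel_mm, "noise_sigma": noise_sigma,
                             "seed": int(seed)})


# ---------------------------------------------------------------------------
# full-session simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionTruth:
    """Ground-truth state of one simulated QA session.

    Each modality pose is the *reported* quantity — the shift of that
    system's isocenter relative to the surface-imaging (phantom) setup
    position — so analysis output can be compared to it directly.
    ``radiation_iso_mm`` is the 3D offset of the radiation isocenter
    (LAT, LNG, VRT) and ``wl_bb_offset_mm`` the residual setup offset of
    the phantom's central BB for the Winston-Lutz series.
    """

    mv: Pose6D = Pose6D()
    kv: Pose6D = Pose6D()
    cbct: Pose6D = Pose6D()
    radiation_iso_mm: tuple = (0.0, 0.0, 0.0)
    wl_bb_offset_mm: tuple = (0.0, 0.0, 0.0)
    wl_axis_jitter_mm: float = 0.0

    @property
    def radiation_shift(self) -> np.ndarray:
        """Expected reported radiation-isocenter shift (LAT, LNG, VRT)."""
        return (np.asarray(self.radiation_iso_mm, float)
                - np.asarray(self.wl_bb_offset_mm, float))


@dataclass
class SessionDataset:
    """All images of one weekly session plus the generating ground truth."""

    ct: VolumeImage
    cbct: VolumeImage
    planar_mv: list
    planar_kv: list
    wl_images: list
    truth: SessionTruth
    phantom: PhantomSpec
    seed: int

    def __post_init__(self) -> None:
        if len(self.planar_mv) != 4 or len(self.planar_kv) != 4:
            raise DomainError("session requires exactly 4 MV and 4 kV images")
        if len(self.wl_images) != 12:
            raise DomainError("session requires exactly 12 Winston-Lutz images")


PLANAR_GANTRY_ANGLES = (0.0, 90.0, 180.0, 270.0)


def simulate_session(truth: SessionTruth = SessionTruth(),
                     phantom: PhantomSpec | None = None,
                     geom: BeamGeometry | None = None,
                     planar_noise: float = DEFAULT_PLANAR_NOISE,
                     volume_noise_fraction: float = DEFAULT_VOLUME_NOISE_FRACTION,
                     ct_voxel_mm: float = 0.6, cbct_voxel_mm: float = 1.0,
                     seed: int = 0) -> SessionDataset:
    """Generate one complete synthetic weekly QA session.

    The phantom is imaged from a single setup: the planning CT at identity
    pose; CBCT / MV / kV with the phantom posed at the *inverse* of each
    modality's true isocenter shift (a system whose isocenter sits at +s
    sees the phantom at -s in its own frame); and the 12 Winston-Lutz
    images with the field axis carrying the radiation-isocenter offset plus
    optional per-image jitter.  All randomness derives from ``seed``.
    """
    from .plan import build_sequence  # deferred: plan imports geometry only

    phantom = phantom or default_phantom()
    geom = geom or BeamGeometry()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(40)]
    rng = np.random.default_rng(np.random.SeedSequence(seeds[0]))
    vol_noise = volume_noise_fraction * (phantom.bb_intensity
                                         - phantom.background_intensity)

    ct = render_volume(phantom, Pose6D(), ct_voxel_mm,
                       noise_sigma=vol_noise, seed=seeds[1])
    cbct = render_volume(phantom, invert_pose(truth.cbct), cbct_voxel_mm,
                         noise_sigma=vol_noise, seed=seeds[2])

    planar_mv, planar_kv = [], []
    for i, g in enumerate(PLANAR_GANTRY_ANGLES):
        gg = geom.replace(gantry_deg=g, collimator_deg=0.0, couch_deg=0.0)
        planar_mv.append(render_planar(phantom, invert_pose(truth.mv), gg,
                                       MV_FIELD, noise_sigma=planar_noise,
                                       seed=seeds[3 + i]))
        planar_kv.append(render_planar(phantom, invert_pose(truth.kv), gg,
                                       KV_FIELD, noise_sigma=planar_noise,
                                       seed=seeds[7 + i]))

    iso_off = np.asarray(truth.radiation_iso_mm, dtype=float)
    bb_off = np.asarray(truth.wl_bb_offset_mm, dtype=float)
    wl_images = []
    for i, cp in enumerate(build_sequence("winston_lutz").control_points):
        gg = geom.replace(gantry_deg=cp.gantry_deg,
                          collimator_deg=cp.collimator_deg,
                          couch_deg=cp.couch_deg)
        # couch rotation physically rotates the phantom about VRT
        a = math.radians(cp.couch_deg)
        couch_rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                              [math.sin(a), math.cos(a), 0.0],
                              [0.0, 0.0, 1.0]])
        pose_rt = (couch_rot, couch_rot @ bb_off)
        # the displaced beam axis passes through the 3D radiation-isocenter
        # offset: its iso-plane trace is the divergent projection of it
        shift = imager_to_iso_plane(project_to_imager(iso_off, gg), gg)
        if truth.wl_axis_jitter_mm > 0:
            shift = shift + rng.normal(0.0, truth.wl_axis_jitter_mm, size=2)
        wl_images.append(render_planar(phantom, pose_rt, gg, WL_FIELD,
                                       field_shift_iso=shift,
                                       noise_sigma=planar_noise,
                                       seed=seeds[11 + i]))

    return SessionDataset(ct=ct, cbct=cbct, planar_mv=planar_mv,
                          planar_kv=planar_kv, wl_images=wl_images,
                          truth=truth, phantom=phantom, seed=seed)
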