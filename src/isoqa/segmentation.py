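"""BB and field-aperture detection in planar images and volumes.

Polarity contract: on planar images the BBs are *dark* features on the
bright open field (transmission convention), so the detectors work on the
inverted signal ``local_background - image``, with the local background
estimated by a grey-value closing (a maximum filter followed by a minimum
filter) whose window is larger than a BB but smaller than field/cube
structure.  Thresholding that signal at a fraction of its extreme value
selects the iso-contour interiors; connected-component labeling separates
the BBs; centroids are intensity-weighted (weights = signal above the
threshold level) and therefore sub-pixel.

In volumes the BBs are *bright* inclusions in the plastic and are
thresholded directly between the plastic level and the peak.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AmbiguityError, DetectionError, DomainError
from .images import PlanarImage, VolumeImage

__all__ = ["LabeledRegion", "FieldMeasurement", "contour_components",
           "match_bbs", "bb_centroids_3d", "field_region"]

#: Matching gate: a predicted BB with no region closer than this is "missing".
DEFAULT_MATCH_GATE_MM = 5.0
#: Total-cost tie margin below which two different assignments are ambiguous.
_TIE_MM = 1e-6


@dataclass
class LabeledRegion:
    """A detected connected region with a sub-pixel/voxel centroid.

    ``centroid`` is in imager mm (2D) or world mm (3D); ``label`` is None
    until assigned by :func:`match_bbs`.
    """

    centroid: np.ndarray
    pixel_count: int
    mean_intensity: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.pixel_count <= 0:
            raise DomainError("region must contain at least one pixel")


@dataclass
class FieldMeasurement:
    """Rectangular-field measurement from 50% edge crossings (imager mm).

    ``edge_positions`` holds the (left, right, bottom, top) crossing
    coordinates along the central profiles; the center is the midpoint of
    opposing edges.  For a collimator-rotated square field the center
    remains exact by symmetry while width/height measure the profile
    diagonal.
    """

    center: np.ndarray
    edge_positions: tuple
    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise DomainError("field width/height must be positive")


def _as_planar(image) -> PlanarImage:
    if isinstance(image, PlanarImage):
        return image
    arr = np.asarray(image, dtype=float)
    from .geometry import BeamGeometry
    geom = BeamGeometry(pixel_pitch_mm=1.0, imager_rows=arr.shape[0],
                        imager_cols=arr.shape[1])
    return PlanarImage(arr, geom)


def contour_components(image, threshold_fraction: float = 0.5,
                       background_window: int = 51) -> list[LabeledRegion]:
    """Detect dark compact regions (BBs) in a planar image.

    Iso-contours the inverted signal at ``threshold_fraction`` of its
    extreme value over the estimated local background and groups interior
    pixels with 8-connected labeling.  Returns anonymous regions with
    intensity-weighted sub-pixel centroids in imager mm.  A constant image
    yields an empty list.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise DomainError("threshold_fraction must lie in (0, 1)")
    img = _as_planar(image)
    arr = img.pixels
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise DomainError("analysis ROI degenerate (smaller than 3x3)")
    if arr.max() == arr.min():
        return []

    w = int(background_window)
    closed = ndimage.minimum_filter(ndimage.maximum_filter(arr, size=w), size=w)
    signal = closed - arr
    peak = signal.max()
    if peak <= 0:
        return []
    thr = threshold_fraction * peak
    mask = signal > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    regions: list[LabeledRegion] = []
    for idx in range(1, n + 1):
        sel = labels == idx
        weights = np.where(sel, signal - thr, 0.0)
        total = weights.sum()
        rows, cols = np.nonzero(sel)
        if total > 0:
            r = (weights.sum(axis=1) @ np.arange(arr.shape[0])) / total
            c = (weights.sum(axis=0) @ np.arange(arr.shape[1])) / total
        else:  # flat plateau exactly at threshold
            r, c = rows.mean(), cols.mean()
        regions.append(LabeledRegion(
            centroid=img.pixel_to_mm(r, c),
            pixel_count=int(sel.sum()),
            mean_intensity=float(arr[sel].mean())))
    return regions


def filter_by_area(regions: list[LabeledRegion], expected_area: float,
                   lo: float = 0.25, hi: float = 4.0) -> list[LabeledRegion]:
    """Keep regions whose pixel/voxel count is within [lo, hi] x expected.

    Rejects stray features (phantom edges, platform) before matching.
    """
    return [r for r in regions
            if lo * expected_area <= r.pixel_count <= hi * expected_area]


def match_bbs(regions: list[LabeledRegion], expected,
              gate_mm: float = DEFAULT_MATCH_GATE_MM) -> list[LabeledRegion]:
    """Assign expected labels to detected regions, one-to-one.

    ``expected`` is a sequence of ``(label, predicted_position)`` with
    positions in the same space (2D imager mm or 3D world mm) as the region
    centroids.  The assignment minimizes total distance over an exhaustive
    search of all ordered region subsets (factorial scale is fine for <= 8
    candidates); every matched pair must lie within ``gate_mm``.

    Raises
    ------
    DetectionError
        If some expected label has no region within the gate.
    AmbiguityError
        If two different assignments tie in total distance (within 1e-6 mm).
    """
    expected = [(lab, np.asarray(pos, dtype=float)) for lab, pos in expected]
    k = len(expected)
    if len(regions) < k:
        raise DetectionError(
            f"only {len(regions)} regions for {k} expected BBs")
    if len(regions) > 8:
        raise DetectionError(
            f"{len(regions)} candidate regions exceed the exhaustive-search "
            "limit of 8; tighten the size filter")

    dist = np.array([[np.linalg.norm(r.centroid - pos) for r in regions]
                     for _, pos in expected])
    for i, (lab, _) in enumerate(expected):
        if dist[i].min() > gate_mm:
            raise DetectionError(
                f"no detected region within {gate_mm} mm of expected BB {lab!r}")

    best_cost, best_perm = np.inf, None
    runner_up = np.inf
    for perm in itertools.permutations(range(len(regions)), k):
        d = dist[np.arange(k), perm]
        if np.any(d > gate_mm):
            continue
        cost = float(np.sum(d**2))
        if cost < best_cost - _TIE_MM:
            runner_up = best_cost
            best_cost, best_perm = cost, perm
        elif abs(cost - best_cost) <= _TIE_MM and perm != best_perm:
            runner_up = min(runner_up, cost)
        elif cost < runner_up:
            runner_up = cost
    if best_perm is None:
        missing = [lab for i, (lab, _) in enumerate(expected)]
        raise DetectionError(f"no complete assignment within the gate for {missing}")
    if runner_up - best_cost <= _TIE_MM:
        raise AmbiguityError("two label assignments tie within 1e-6 mm")

    out = []
    for (lab, _), ridx in zip(expected, best_perm):
        r = regions[ridx]
        out.append(LabeledRegion(centroid=r.centroid, pixel_count=r.pixel_count,
                                 mean_intensity=r.mean_intensity, label=lab))
    return out


def bb_centroids_3d(volume: VolumeImage, expected,
                    threshold_fraction: float = 0.5,
                    gate_mm: float = DEFAULT_MATCH_GATE_MM,
                    bb_diameter_mm: float = 7.5) -> list[LabeledRegion]:
    """Locate and label BBs in a volume; centroids in world mm.

    Thresholds between the plastic level (volume median — the cube fills
    most of the grid) and the intensity peak, labels 26-connected
    components, size-filters against the expected sphere voxel count, and
    requires exactly one component per expected BB.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise DomainError("threshold_fraction must lie in (0, 1)")
    expected = [(lab, np.asarray(pos, dtype=float)) for lab, pos in expected]
    vox = volume.voxels.astype(float)
    plastic = float(np.median(vox))
    peak = float(vox.max())
    if peak <= plastic:
        raise DetectionError("volume shows no BB contrast above the plastic level")
    thr = plastic + threshold_fraction * (peak - plastic)
    mask = vox > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))

    vsize = float(np.prod(volume.spacing))
    expected_count = (4.0 / 3.0) * np.pi * (bb_diameter_mm / 2.0) ** 3 / vsize
    regions = []
    for idx, slc in enumerate(ndimage.find_objects(labels, n), start=1):
        if slc is None:
            continue
        sel = labels[slc] == idx
        cnt = int(sel.sum())
        if not 0.25 * expected_count <= cnt <= 4.0 * expected_count:
            continue
        weights = np.where(sel, vox[slc] - thr, 0.0)
        com = ndimage.center_of_mass(weights)
        com_global = [c + s.start for c, s in zip(com, slc)]
        regions.append(LabeledRegion(
            centroid=volume.index_to_world(com_global), pixel_count=cnt,
            mean_intensity=float(vox[slc][sel].mean())))
    if len(regions) != len(expected):
        raise DetectionError(
            f"found {len(regions)} BB candidates, expected {len(expected)}")
    return match_bbs(regions, expected, gate_mm=gate_mm)


def _cross_from_outside(profile: np.ndarray, thr: float):
    """50% crossings scanned inward from both ends (robust to interior dips).

    Returns fractional indices (left, right) by linear interpolation, or
    None if the profile never reaches the threshold.
    """
    above = profile >= thr
    if not above.any():
        return None
    i = int(np.argmax(above))            # first >= thr from the left
    j = len(profile) - 1 - int(np.argmax(above[::-1]))
    if i == 0 or j == len(profile) - 1:
        return None                      # field clipped by the imager edge
    left = i - 1 + (thr - profile[i - 1]) / (profile[i] - profile[i - 1])
    right = j + (profile[j] - thr) / (profile[j] - profile[j + 1])
    return left, right


def field_region(image, band_half_px: int = 3) -> FieldMeasurement:
    """Measure a rectangular open field: 50% edge crossings and center.

    Levels: background from the outer image border, open-field from a high
    percentile; orthogonal profiles through the approximate field center
    (averaged over a small band for noise suppression) are scanned from the
    outside in, so BB dips inside the field cannot masquerade as edges.
    """
    img = _as_planar(image)
    arr = img.pixels
    border = np.concatenate([arr[0], arr[-1], arr[:, 0], arr[:, -1]])
    bg = float(np.median(border))
    rough = float(np.percentile(arr, 99.9))
    if rough <= bg:
        raise DetectionError("no open field above background level")
    # typical in-field level: median of clearly-open pixels, so the estimate
    # is insensitive to how much of the frame the field covers
    open_level = float(np.median(arr[arr >= bg + 0.75 * (rough - bg)]))
    thr = bg + 0.5 * (open_level - bg)

    mask = arr > thr
    if not mask.any():
        raise DetectionError("no pixels above the 50% field level")
    rc, cc = ndimage.center_of_mass(mask)
    r0, c0 = int(round(rc)), int(round(cc))

    b = band_half_px
    row_prof = arr[max(0, r0 - b):r0 + b + 1, :].mean(axis=0)
    col_prof = arr[:, max(0, c0 - b):c0 + b + 1].mean(axis=1)
    h = _cross_from_outside(row_prof, thr)
    v = _cross_from_outside(col_prof, thr)
    if h is None or v is None:
        raise DetectionError("fewer than 4 field-edge crossings found")

    left_uv = img.pixel_to_mm(rc, h[0])
    right_uv = img.pixel_to_mm(rc, h[1])
    top_uv = img.pixel_to_mm(v[0], cc)       # low row index = +v edge
    bottom_uv = img.pixel_to_mm(v[1], cc)
    center = np.array([(left_uv[0] + right_uv[0]) / 2.0,
                       (top_uv[1] + bottom_uv[1]) / 2.0])
    width = float(right_uv[0] - left_uv[0])
    height = float(top_uv[1] - bottom_uv[1])
    return FieldMeasurement(center=center,
                            edge_positions=(float(left_uv[0]), float(right_uv[0]),
                                            float(bottom_uv[1]), float(top_uv[1])),
                            width_mm=width, height_mm=height)
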