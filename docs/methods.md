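# Methods

`isoqa` implements an automated, single-setup isocenter-congruence QA
procedure for stereotactic radiosurgery linacs, together with a synthetic
image generator that stands in for the treatment machine.  This note
records the models, conventions, numerical choices and limitations.

## Coordinate conventions

All quantities live in one room frame (IEC 61217-like): **+X = LAT**
(lateral), **+Y = LNG** (longitudinal, toward the gantry), **+Z = VRT**
(vertical, up).  The gantry rotates about +Y, the couch about +Z, the
collimator about the beam axis.  At gantry 0 the source sits at
`(0, 0, +SAD)` and the beam points down.

A 6D shift is `(VRT, LNG, LAT)` in mm plus `(pitch, roll, Rtn)` in degrees
— rotations about LAT, LNG and VRT respectively.  The rotation operator is
composed as `R = Rz(Rtn) · Rx(pitch) · Ry(roll)` (roll first).  No
composition order is canonical for couch-style corrections; at the
sub-degree rotations this QA regime sees, the orders differ by less than
1e-4 mm at the phantom radius, but a fixed order is required for exact
round-trip tests, so one is declared and used everywhere.  Rotations with
magnitude ≥ 45° are rejected: they are outside any QA scenario and keep
the Euler decomposition unique.

**Sign convention.**  A positive reported shift means the tested system's
isocenter lies on the positive-axis side of the surface-imaging (OSMS)
setup position of the phantom.  Estimators that naturally produce the
*apparent phantom pose* in an imaging system's frame (planar fit, CBCT
registration — i.e. couch-correction-style outputs) report the *inverse*
pose.  For the Winston-Lutz result, `phantom_shift = radiation_isocenter −
bb_position` under the same convention.

## Imaging model

Projection is central (divergent): a point is projected from the source
onto the plane perpendicular to the beam axis at distance SID; the
isocenter maps to the imager origin at every gantry angle.  Defaults
SAD = 1000 mm, SID = 1500 mm (magnification 1.5), 0.336 mm pixels on a
1024×1024 imager; all configurable.  Imager u runs along the
gantry-rotated +X, v along +Y; pixel (0, 0) is the array corner, with
coordinates at pixel centers.

## Phantom and synthetic data generator

The phantom is a 15 cm plastic cube with five 7.5 mm ceramic BBs: one at
the center, four placed asymmetrically with the furthest 45 mm off-center.
The exact off-center coordinates are not a published property of the
physical phantom; the default layout (`a1` (20, 12, −16), `a2`
(−24, −18, 10), `a3` (14, −26, 22), `a4` (−20, 35, 20) mm) was chosen once
so that the four off-center BBs occupy distinct octants at 28–45 mm radius
and no two BBs share a coordinate on any axis — the asymmetry that makes a
6D pose identifiable from projections.  The layout is configurable.

Planar images are transmission radiographs: an open rectangular field
(MV 100 mm MLC, kV 110 mm blades, ball-and-field 25 mm) with a Gaussian
penumbra (σ = 0.5 mm at iso — some finite penumbra is needed for
sub-pixel edge localization), attenuated by exact analytic line integrals
through the cube (slab intersection) and the BB spheres (chord length).
Material values are relative attenuations per mm (plastic 0.0015,
BB 0.070), giving BB dips of ≈ 40% of the local open level.  Open field is
bright; attenuated structures are dark — the polarity every detector
assumes.  Additive Gaussian noise (default σ = 1% of the open-field
level) is seeded; rendering is bit-reproducible for fixed arguments.

Volumes (CT at 0.6 mm, CBCT at 1.0 mm voxels by default) are rendered
directly as voxelizations with linear partial-volume ramps one voxel wide
at material surfaces; no projection/reconstruction chain is simulated
because only the reconstructed volume is ever analyzed.  Volume noise
defaults to 2% of the BB-background contrast.

A simulated weekly session contains the planning CT (identity pose), the
CBCT, four cardinal-angle MV + kV pairs and the 12 ball-and-field images.
Each modality's true isocenter shift `S` is realized by posing the phantom
at `S⁻¹` in that modality's frame; the radiation-isocenter offset is
realized by passing each field's central axis through the offset point
(its imager trace is the divergent projection of that point), with
optional per-image jitter emulating walkout.

**What the generator does not emulate:** scatter, beam hardening, detector
lag/ghosting, gantry sag and imager-arm flex, couch-walkout mechanics, the
leveling platform, and OSMS camera imagery (the OSMS alignment enters only
as the phantom's true pose).  Passing tests therefore demonstrate the
correctness and noise behavior of the *analysis*, not the physics of any
particular machine.

## Detection

*BBs in 2D.*  The local background is estimated by a grey-value closing
(maximum filter then minimum filter, 51 px window — larger than a BB,
smaller than field structure); the inverted signal is iso-contoured at 50%
of its extreme value, interior pixels are 8-connected-labeled, and
centroids are intensity-weighted with weights equal to the signal above
the threshold level (sub-pixel, and unbiased for the symmetric BB
profile).  Candidate regions outside [25%, 400%] of the projected BB disc
area are discarded — this removes stray features such as phantom edges.
Thresholding the closed-minus-original signal selects exactly the interior
of the 50% iso-contour that a marching-squares contour extraction would
delineate on the pixel grid.

*Label assignment* is an exhaustive minimum-cost matching of detections to
predicted positions (≤ 8 candidates, factorial search is trivial), gated
at 5 mm (stated at the isocenter plane; scaled by the magnification on the
imager).  Ties within 1e-6 mm raise an ambiguity error rather than an
arbitrary choice.  Predictions use the nominal (unshifted) layout, which
is valid because true shifts (≲ 2 mm) are far inside the gate.

*BBs in 3D* are thresholded at 50% between the plastic level (the volume
median — the cube fills most of the grid) and the peak, 26-connected
labeled, size-filtered against the sphere voxel count, and
intensity-weighted for sub-voxel world-frame centroids.

*Field edges.*  Background from the image border, open level from the
median of clearly-open pixels; edges are the 50% crossings of orthogonal
profiles through the approximate field center, averaged over a ±3 px band
and scanned **from the outside in**, so the central BB dip (which can fall
below the 50% level) can never masquerade as an edge.  The field center is
the midpoint of opposing crossings; for a collimator-rotated square field
the center remains exact by symmetry while width/height measure the
profile diagonal.

## Estimation

*Triangulation.*  Each labeled detection back-projects to the ray from the
source through the imager point; the BB position is the least-squares
point minimizing summed squared perpendicular distances (3×3 normal
equations).  At least two rays separated by ≥ 10° of line angle are
required; a normal-matrix condition number above 1e8 is rejected.  The
gantry 0°/180° pair is correctly rejected: the two rays are collinear.

*Rigid fit.*  Labeled point sets are superposed by centroid alignment and
SVD orthogonal decomposition with the determinant +1 constraint, so a
reflection is never returned even for noisy near-coplanar sets; the pose
is then decomposed into the six reported components.  Collinear nominal
sets (second singular value < 1e-9 relative) are rejected as degenerate.

*Planar 6D pipeline.*  Detections from all four gantry angles are
triangulated per label and a single rigid fit against the nominal layout
is solved — one well-posed least-squares problem instead of merging four
per-angle estimates (per-image matched centroids remain available as
diagnostics).  Whether commercial tools average per-angle results is not
public; the joint fit is validated against simulator ground truth.

*CBCT↔CT.*  BB-centroid rigid registration; grey-value registration is
deliberately not implemented, since the phantom's information content is
its five BBs (this mirrors phantom-priority online matching).  An RMS
residual above 1 mm sets a quality flag.

*Radiation isocenter.*  Each ball-and-field image's measured field center
back-projects to a central-axis ray; the radiation isocenter is the
least-squares point over all 12 rays.  Walkout per rotation axis is the
maximum point-to-ray distance within that axis's image subgroup (the
shared gantry/collimator/couch = 0 reference image belongs to all three
subgroups); a diameter-style alternative (max pairwise ray-to-ray
distance) is selectable via `walkout_mode="diameter"`.  Couch rotations
physically move the BB, so the BB's 3D position is triangulated from the
couch-0 gantry-sweep images only; couch-image deviations inform only the
couch walkout.  The exact objective used by commercial ball-and-field
analysis software is not public; the least-squares-over-rays reading of
"minimizing the deviations" is validated against simulation ground truth
and a brute-force 0.005 mm grid search.

## Statistics

*Wilcoxon signed-rank (one-sample, two-sided).*  Exact for n ≤ 25 via
dynamic programming over the conditional distribution of the positive
midrank sum given the observed (possibly tied) ranks — identical to
enumerating all 2ⁿ sign assignments.  Zero differences are dropped before
ranking by default (Pratt handling available).  The two-sided p doubles
the smaller tail and is capped at 1.  Above n = 25, a normal approximation
with conditional moments `E W⁺ = Σr/2`, `Var W⁺ = Σr²/4` (which absorbs
tie corrections) and a 0.5 continuity correction is used; at n = 20 it
agrees with the exact p to < 0.01.

*Trend summary* reports per modality-axis the sample mean, SD (n−1) and
the signed extreme (largest magnitude, sign kept), plus the Wilcoxon p
against zero pooled over all weeks (the pooling choice is an assumption,
documented here).

*Tolerances.*  SRS action levels 1.0 mm / 1.0° per axis (≤ passes at the
boundary) and a vendor congruence check: every translational shift of
every modality within 0.75 mm.

*Drift detection* flags a week when any modality-axis departs from the
running median of all prior weeks by more than 0.4 mm / 0.3° (the
stable-period single-direction envelope), requiring ≥ 5 prior weeks of
baseline.  This rule is a beyond-protocol addition — weekly trend charts
are traditionally judged by eye.

## Problem sizes and reproducibility

Default study sizes, chosen once as realistic desk-scale replications: 200
random poses for parameter-recovery studies, 100 datasets for the Wilcoxon
enumeration check, 17 weekly sessions for the drift emulation (excursions
of +0.8 mm LAT injected in weeks 14–15 on MV and kV), and 10 repeated
sessions for the uncertainty study.  All randomness flows from a single
integer seed through `numpy.random.SeedSequence` spawning; reports carry a
configuration hash, the seed and the software version, and identical
inputs produce byte-identical report JSON.

## Known limitations

- The imager is assumed perfectly centered on the nominal beam axis;
  imager-offset calibration maps (IsoCal-style) are out of scope, so
  field-center rays are absolute rather than BB-relative.
- Intensity-based volume registration, MLC leaf-level analysis, film
  dosimetry and machine control (XML files are documentation artifacts,
  not machine-ingestible scripts) are out of scope.
- The acquisition XML dialect is a minimal documented schema, not a
  vendor format.
- Detection assumes the rendered polarity contract (dark BBs on a bright
  field; bright BBs in volumes); real images with inverted LUTs must be
  converted on import.
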