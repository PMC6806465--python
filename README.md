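# isoqa

Single-phantom, automated **isocenter-congruence QA** for stereotactic
radiosurgery (SRS) linacs.

Modern SRS delivery relies on several nominally coincident isocenters: the
MV portal imager (EPID), the kV on-board imager, the cone-beam CT, the
optical surface monitoring system (OSMS) used for setup, and the radiation
beam itself.  Submillimeter disagreements between them translate directly
into targeting error, so SRS programs verify their congruence weekly
against tolerances of 1.0 mm / 1.0° (and a 0.75 mm vendor congruence
specification).  `isoqa` analyzes one single setup of a five-BB cube
phantom — planar MV/kV images at the four cardinal gantry angles, a CBCT
registered to the planning CT, and a 12-image Winston-Lutz
(ball-and-field) series — and reports, relative to the OSMS setup
position:

- the **6D shift** (VRT, LNG, LAT translations; pitch, roll, Rtn
  rotations) of the MV, kV and CBCT isocenters,
- the **3D radiation isocenter** with gantry/collimator/couch walkouts,
- tolerance flags, weekly **trend statistics** (mean, SD, signed extreme,
  one-sample Wilcoxon signed-rank p) and running-median **drift flags**.

Because no public image sets exist for this phantom, the package includes
a first-class synthetic generator (`isoqa.phantom`) that renders every
image the pipeline consumes — divergent-projection radiographs with exact
line integrals through cube and BBs, and voxelized CT/CBCT volumes —
under arbitrary 6D poses with seeded noise and retained ground truth.

## Method at a glance

For planar modalities, the five BBs are contoured (local-background
inversion, 50% iso-threshold, connected-component labeling,
intensity-weighted sub-pixel centroids), labeled by minimum-cost matching
to predicted positions, back-projected to source rays and triangulated
across gantry angles; the 6D shift is the inverse of the rigid
(Kabsch-style, proper-rotation) fit of the triangulated set to the nominal
layout.  CBCT-to-CT uses the same rigid fit on 3D BB centroids.  For the
Winston-Lutz series, each image yields the 2D deviation `field − BB` at
the isocenter plane; the radiation isocenter **r** minimizes

    Σᵢ ‖ (I − dᵢdᵢᵀ)(r − oᵢ) ‖² ,

the summed squared perpendicular distances to the twelve back-projected
central-axis rays (origin oᵢ, direction dᵢ), and each axis's walkout is
the maximum point-to-ray distance within that axis's image subgroup.
Full details and conventions: [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a weekly session whose MV isocenter is shifted +0.8 mm LAT and
rotated +0.3° Rtn, then analyze it:

```python
import numpy as np
from isoqa import Pose6D, SessionTruth, simulate_session, run_weekly_qa

truth = SessionTruth(mv=Pose6D(lat_mm=0.8, rtn_deg=0.3))
session = simulate_session(truth=truth, seed=7)   # CT, CBCT, 4 MV+4 kV, 12 W-L
report = run_weekly_qa(session)

print({k: round(v, 3) for k, v in report.mv.pose.to_dict().items()})
print("congruence pass:", report.flags["congruence"])
```

prints

```
{'vrt_mm': 0.0, 'lng_mm': -0.0, 'lat_mm': 0.801, 'pitch_deg': -0.007, 'roll_deg': -0.01, 'rtn_deg': 0.301}
congruence pass: False
```

— the injected 0.8 mm / 0.3° MV shift is recovered to ≈ 0.001 mm / 0.01°
under the default 1% image noise, and the 0.8 mm LAT shift correctly
breaches the 0.75 mm vendor congruence check (while still passing the
1.0 mm SRS action level).

The same workflow is scriptable from the shell:

```bash
isoqa plan build --kind winston_lutz --out wl.xml   # 12-point acquisition template
isoqa simulate --out week01 --seed 7 --mv-lat 0.8 --mv-rtn 0.3
isoqa analyze week01 --out week01.json
isoqa trend week*.json --out trend/                 # mean/SD/extreme, Wilcoxon p, drift flags
isoqa repeatability --n 10 --seed 3
```

## Layout

| module | contents |
| --- | --- |
| `isoqa.geometry` | room frame, 6D poses, divergent projection model |
| `isoqa.phantom` | phantom spec, planar/volume renderer, session simulator |
| `isoqa.segmentation` | BB and field-edge detection, label matching |
| `isoqa.pose` | triangulation, rigid fit, planar/CBCT 6D shift pipelines |
| `isoqa.winston_lutz` | ball-and-field deviations, radiation isocenter, walkouts |
| `isoqa.stats` | Wilcoxon test, trend summary, tolerance and drift flags |
| `isoqa.plan` | acquisition sequence templates and XML serialization |
| `isoqa.workflow` | weekly orchestration, session I/O, reports, CLI backend |
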