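# hiprom

Prosthetic impingement analysis for total hip arthroplasty (THA) planning:
given a femoral stem, modular head and acetabular liner, `hiprom` maps the
cup orientations (radiographic inclination α and anteversion β) at which the
reconstructed hip meets user-defined range-of-motion targets without the
stem neck striking the liner rim.  It is aimed at surgical-planning
engineers and biomechanics researchers who need patient- and implant-
specific acetabular safe zones rather than a generic one.

## The model

Prosthetic range of motion before neck–liner impingement is governed by a
cone overlap.  The liner rim circle lies on the cavity sphere of radius *r*
at polar angle φ from the outward cup axis, cos φ = (d − r)/r for a cavity
of depth *d* (φ = 90° for a hemispherical liner).  The neck, of width *n*
at the impingement level, subtends a half-angle γ at the head centre,
sin γ = n/(2r).  The hip is impingement-free exactly while the neck axis
stays within φ − γ of the cup axis; the maximum internal/external rotation
at a given flexion/extension is the first exit of the neck axis from that
cone, which is closed-form because axial rotation sweeps the neck on a
circular cone about the femoral shaft axis.

The catch is *n*: modern trapezoidal necks are not cylinders, so *n* varies
with where and at which approach direction the rim meets the neck.
`hiprom` therefore measures *n* by an automated mesh-collision simulation —
driving flexion-then-internal-rotation (and extension-then-external-
rotation) to first interference at every cup orientation of a grid, at stem
anteversions −40°…60° in 20° steps — and interpolates the scattered samples
with exact thin-plate splines so that *n*(α, β, stem anteversion) can be
queried anywhere.  Substituting the interpolated *n* into the cone formula
gives impingement boundaries for any combined target, e.g. 30° IR @ 90°
flexion and 10° ER @ 10° extension, drawn on a green/red cup-orientation
map.  An independent mesh-interference oracle — pure collision bisection,
no database, no spline, no formula — verifies the analytical boundaries.

Cup angles use Murray's radiographic definitions; stem placement defaults
are neck–shaft angle 125°, stem flexion 0°, stem adduction 6°.  No
proprietary implant geometry is included: a parametric synthetic implant
family (cylindrical reference plus a trapezoidal-neck stem with 28–40 mm
heads and −4…+8 mm offsets) is generated by the package.

## Worked example

```sh
hiprom fixtures --out fixtures
hiprom build-db --implant fixtures/trapezoidal_head32.yaml \
    --grid-step 10 --slices 0,20,40 --out db
hiprom solve --implant fixtures/trapezoidal_head32.yaml --db db \
    --target "30IR@90FL,10ER@10EX" --stem-av 10 --out boundary.csv
hiprom render --implant fixtures/trapezoidal_head32.yaml --db db \
    --stem-av 10 --out zone.png
```

The `build-db` step prints `database: 182 samples -> db` (one row per cup
orientation that impinged within the sweep, with the measured neck width
and contact site).  `render` prints `green area 604 deg^2 -> zone.png`:
the area of cup orientations satisfying both targets at stem anteversion
10°, drawn green with the two impingement boundaries and a black reference
box at 30–50° inclination × 10–30° anteversion.  `boundary.csv` holds the
solved curves, e.g. the flexion-side row `flexion_side,40.000000,19.917046`
says that at 40° inclination the cup needs ≥ 19.9° anteversion to reach 30°
IR at 90° flexion.

The same study from Python:

```python
import numpy as np
from hiprom import NeckWidthDatabase, ROMTarget, StemPose, evaluate_map
from hiprom.fixtures import trapezoidal_assembly

assembly = trapezoidal_assembly(head_diameter_mm=32)
db = NeckWidthDatabase.build(assembly, slices=(10.0,),
                             alphas=np.arange(0, 61, 10.0),
                             betas=np.arange(0, 61, 10.0))
zone = evaluate_map(ROMTarget(30, 90, 10, 10), StemPose(anteversion_deg=10),
                    assembly, db, step_deg=2.0)
print(zone.green_area_deg2)   # 616.0
```

Larger heads enlarge the zone (28→40 mm: 432 → 932 deg² under the same
conditions); higher stem anteversion shifts it toward lower cup
anteversion; short (−4 mm) and skirted extra-long (+8 mm) head offsets
shrink it, the latter because the liner engages the trunnion.

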