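# Methods

## Model

The prosthetic hip is reduced to three rigid parts sharing one centre of
rotation (the femoral head centre, the assembly origin): a femoral stem
whose neck/trunnion geometry is swept from parametric cross-sections, a
spherical head congruent with the liner cavity, and an acetabular liner
modelled as the solid of revolution of a meridian profile (spherical cavity
of radius *r* and depth *d*, flat annular rim face, cylindrical outer
wall).  Impingement is contact between the liner rim and the stem; bony
impingement, soft tissue, joint contact force and wear are outside the
model.

**Frames and conventions.**  Right-handed pelvic frame, X lateral
(operative side), Y anterior, Z superior; a right hip is modelled and left
hips are handled by mirroring anteversions at the input.  Cup orientation
follows the radiographic (Murray) convention: the outward cup axis is
u = (sin α cos β, sin β, −cos α cos β).  Femoral placement applies, in
order: the neck–shaft angle (inside the stem geometry), stem flexion,
adduction (default 6°, natural standing adduction), and stem anteversion
about the femoral shaft axis (positive rotates the neck anteriorly).
Motion is primary-then-secondary: flexion/extension about the pelvic
medio-lateral axis through the head centre, then internal/external rotation
about the current femoral shaft axis.  Everything is composed with rotation
matrices/quaternions; Euler angles are never extracted mid-pipeline, so
deep-flexion poses are not degenerate.

**Cone overlap.**  The rim circle lies on the cavity sphere at polar angle
φ from u, cos φ = (d − r)/r (hemisphere: φ = 90°; a shallow liner's rim
sits past the equator and allows more tilt, a lipped liner less).  A neck
of width *n* at the impingement level subtends γ at the origin,
sin γ = n/(2r).  The hip is impingement-free while angle(m, u) ≤ φ − γ,
where m is the distal neck axis.  During axial rotation m traces a cone
about the shaft axis, so m·u is sinusoidal in the rotation angle and the
first exit from the safe cone is closed-form; the achieved secondary
rotation is that first exit, 0 if any sampled station of the primary
motion already violates the cone (3° sampling), and capped at a 170°
sentinel when the cone is never exited (no physical joint rotates
further).

**Neck width at the impingement level.**  *n* is measured from the
collision simulation at the first-interference event as the chord the rim
must clear: n = 2 r sin(φ − angle(m, u)) at contact.  For cylindrical necks
this equals the section diameter, making the cone formula exact; for
trapezoidal sections it is the silhouette width actually engaged (first
contact typically happens at a section corner, off the plane through the
neck and cup axes, so a width measured through the contact point would
overstate the obstruction by several degrees of boundary position — the
oracle-equivalence tests arbitrated this choice).  The geometric
point-measure (twice the contact point's distance to the neck axis) is
retained as `neck_width_at_contact` for site classification and cylinder
checks.

**Database and interpolation.**  For each motion side (flexion+IR,
extension+ER) and each stem-anteversion slice (−40…60° step 20°), the
motion is driven at every cup orientation of a 0–60 × 0–60 grid: coarse 2°
steps to first mesh interference, bisection refinement to 0.05°, one
(α, β, n, contact site) sample per orientation.  The flexion-side secondary
rotation is driven at 90° flexion and the extension side at 10° extension
(the canonical anterior/posterior test positions; the primary angle is an
explicit parameter recorded in the database metadata, since the contact
station depends on it).  Orientations that never impinge within the 170°
sweep are censored; orientations already interpenetrating at neutral are
degenerate and excluded with a warning.  Each (side, slice) sample set is
interpolated by an exact thin-plate spline (kernel ρ² log ρ plus an affine
tail, zero smoothing — `scipy.interpolate.RBFInterpolator`), which
interpolates knots to 1e−9 and reproduces affine functions exactly;
queries at arbitrary stem anteversion blend the two bracketing slices
linearly, matching the validation design that probes slice midpoints, and
are clamped to the stem's physical width range.  A query outside the cup
grid or the slice range is an error, never an extrapolation.

**Boundaries and safe zone.**  For a combined target (IR@FL, ER@EX) the
boundary solver root-finds, per inclination, the anteversion where the
achieved secondary rotation equals the target (Brent, 0.01°), taking the
*principal* crossing: scanning up in anteversion, the first
unsatisfied→satisfied crossing on the flexion side and the first
satisfied→unsatisfied on the extension side — exactly the two curves of
the colour map, where orientations left of the flexion curve and right of
the extension curve impinge.  Secondary crossings at extreme combined
anteversion border the degenerate neutral-interpenetration region and are
reported separately (`all_crossings`), not as the boundary.  The safe-zone
map classifies cell centres of a 1° grid (area = cell count × step²,
square degrees) and renders green/red with both curves and a black
reference box at 30–50° inclination × 10–30° anteversion.

## Collision detection

`python-fcl`-style general mesh collision is not required: all rotations
are about the origin, so distances from the origin are invariants.  The
detector tests (a) the stem mesh's vertices — prefiltered once to the
distance band that can reach the liner — for containment in the liner's
revolved solid, a 2-D point-in-polygon test on the same meridian polygon
the liner mesh is built from, and (b) the liner rim-circle vertices for
containment in the stem's swept-profile solid (closed-form rounded-
rectangle/frustum sections), so a sharp rim edge pressing into a flat neck
face is not missed.  Because the contacting surfaces are curved, the first
vertex penetrates within ~(e/2)²/(2ρ) of true contact (e = edge length,
ρ = local radius), about 0.01 mm at the default 64 segments/revolution —
an angular detection lag well under 0.05°.  Tests double the resolution
and verify located limits move by < 0.1°.

## Oracle and validation

The oracle locates boundaries by bisecting cup anteversion (to 0.02°) on
the predicate "the full target motion, sampled at 1.5°, completes without
interference", using only the collision detector.  It shares the
kinematics module deliberately, so the comparison isolates formula and
interpolation error, not convention error.  The validation experiment uses
the worst-case assembly — the largest fixture head (40 mm) engaged at the
shortest offset (−4 mm), which pushes contact to the most proximal,
fastest-varying neck geometry — with boundaries at the five midpoint stem
anteversions (−30, −10, 10, 30, 50°) on a 2° inclination grid.  Curves are
compared by nearest-point distance decomposed into inclination and
anteversion components; a matched-coordinate pairing would multiply the
true curve separation by the local boundary slope and diverge on the
near-vertical extension curve (the matched-inclination anteversion delta
is still reported per configuration).  Measured maxima for the default
configuration: 0.9° inclination, 1.0° anteversion; on-slice anteversions
show smaller deltas than midpoints, confirming the cross-slice blend as
the dominant error term.

## Synthetic implant family

No commercial geometry ships with the package; fixtures are synthetic by
construction.  The trapezoidal stem has neck full widths 11 → 20.6 mm
(proximal-distal) and 12 → 18 mm (anterior-posterior) from the trunnion
junction to the shoulder — inside the ~11–22 mm span of modern trapezoidal
stems — with 2 mm corner radius, 125° neck–shaft angle, and a 16 mm × 4 mm
trunnion/skirt frustum.  The trunnion is deliberately much wider than the
distal neck: with a +8 mm (skirted) head it is what the rim engages, and
its width must clearly exceed the neck's corner chord (~13.5 mm) for that
engagement to cost motion.  Heads are 28/32/36/40 mm with offsets
−4/0/+4/+8 mm; each liner is hemispherical and congruent with its head,
with a 5 mm rim annulus.  The cylindrical reference (constant 12 mm
circular neck, trunnion flush) is the geometry for which the formula is
exact and anchors the formula-only accuracy tests.  The femoral diaphysis
is not meshed: the rim circle lies one head radius from the origin and
cannot reach it; the shaft axis still defines the rotation axes.

What the synthetic family does not emulate: exact commercial neck
free-form surfaces, liner chamfers and elevated-rim liners, anatomic
(non-radiographic) version conventions, pelvic tilt.  Passing tests
therefore demonstrate the pipeline's internal accuracy (formula +
interpolation vs direct collision on the same geometry) and the direction
and ordering of parameter effects, not millimetre-exact predictions for
any commercial implant.

## Problem sizes and numerical choices

Default analysis sizes: database cup grid 10°, six anteversion slices,
mesh resolution 64 segments/revolution, boundary grid 2°, map grid 1°.
These keep a full database build under ~20 s and the complete validation
experiment around a minute on one CPU while leaving the measured
analytical-vs-oracle disagreement well below the interpolation error they
bound.  Ties and degenerate inputs: duplicate TPS knots are dropped before
fitting; fewer than three or collinear knots are an error; γ ≥ φ raises a
geometric-infeasibility error in scalar evaluation and classifies as
zero-motion (red) in grid evaluation; when both trunnion and neck contact
are possible the first contact in motion order wins, in both the sweep and
the oracle.  The pipeline has no stochastic step: rebuilding the database,
boundaries and validation report is bit-identical, and output files are
written with fixed float formatting to keep them diff-able.
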