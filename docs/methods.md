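# Methods

## Model and assumptions

The package treats elbow valgus braking as a purely kinematic, rigid-body
problem. Ligament bundles and tendons are inextensible-geometry probes:
each is a straight chord between a humerus-fixed origin and an ulna-fixed
insertion, digitized at the reference posture (90° flexion, 0° valgus,
neutral rotation). Strain is the percent change of chord length relative to
that posture, `strain% = (L_T − L_ST)/L_ST × 100`, so strain at the
reference pose is identically zero by construction — the pipeline
guarantees this bit-exactly because a zero-angle rotation is implemented as
a true identity and the reference lengths are measured from the same
digitized coordinates.

Assumptions inherited by every result:

* **Straight fibers, no wrapping.** Only endpoint pairs are digitized;
  chord length stands in for fiber length. Strains of fibers that wrap
  bone at extreme flexion are overestimated in magnitude.
* **Pure rotations about fixed anatomical axes.** Flexion and valgus are
  modeled as rotations about humerus-fixed axes through the epicondylar
  midpoint; joint translation, laxity, and the in-vivo migration of the
  flexion axis are not modeled.
* **No mechanics.** Forces, torques, material properties, muscle activity
  and gravity are outside the model; "taut" and "shortened" are geometric
  statements only.

## Anatomical frame

The glenohumeral rotation center is the center of a least-squares sphere
fitted to the humeral-head cloud. The default fit is the algebraic
(linearized) least-squares solution; an optional geometric refinement
(Levenberg–Marquardt on radial residuals, started from the algebraic
solution) is available and agrees with the algebraic center to well under
the digitizer noise at realistic cloud sizes. Degenerate clouds are
rejected when the condition number of the (mean-centered) normal equations
exceeds 1e8, which catches coplanar and collinear configurations.

The frame is: origin at the midpoint of the epicondyle tips; Y toward the
rotation center; X along `(le − me) × (ghc − me)`, the epicondylar-plane
normal; Z = X × Y. Because the medial/lateral roles of the two epicondyle
arguments are fixed, this normal points anteriorly on a left elbow and
posteriorly on a right one — which is exactly the orientation that makes a
*positive X rotation a valgus rotation on both sides*, with no explicit
sign flip. The mirror asymmetry has to surface somewhere: a reflection
flips the valgus axis but commutes with rotations about its own normal, so
it is the *flexion sense* about Z that is side-dependent. The posing step
therefore rotates by `+(flexion − 90°)` about Z on left elbows and by
`−(flexion − 90°)` on right ones. A right-sided specimen that is the exact
x-reflection of a left one reproduces the left specimen's strains to 1e-9,
which is the invariant this convention is chosen to satisfy.

### Where the rotation axes pass through

Axis *directions* follow from the landmark definitions, but the valgus
result also depends on where the axes intersect the humerus. Both axes are
taken to pass through the epicondylar midpoint — the conventional elbow
center. This is a modeling choice, configurable in principle by
substituting another frame origin, and should be remembered when comparing
absolute strain magnitudes across studies.

### Rotation order

Flexion is applied before valgus, both about humerus-fixed axes. For the
10° valgus used here the order effect is second-order;
`rotation_order="valgus_then_flexion"` is provided for sensitivity checks,
and both orders coincide exactly at 0° valgus (tested).

## Synthetic specimens

No digitized cadaver coordinates ship with the package, so a seedable
generator produces anatomically plausible landmark sets. Conventions (left
elbow): humeral shaft along +Y, epicondylar axis along X with the medial
epicondyle at −X, forearm at the digitized 90°-flexion posture along +Z
(anterior). Defaults are representative adult dimensions — humeral head
radius 22.5 mm, epicondyle width 55 mm, humerus length 290 mm — chosen by
the implementer and configurable; none is asserted to match any particular
cadaver.

The humeral-head cloud is 40 points uniform on the proximal hemisphere with
isotropic Gaussian noise of sd 0.23 mm, the stated precision of the
digitizing arm (the precision is reported as a scalar; the isotropic
Gaussian is our modeling choice). At these settings the algebraic sphere
fit recovers the true center with a mean error of about 0.15 mm over
1000 Monte-Carlo draws; the error distribution has a tail (hemisphere-only
coverage weakens the proximal-distal constraint), so the 0.3 mm recovery
bound is asserted on the expectation, not per draw.

Attachment sites are placed deterministically: a base layout plus fixed
group-conditional shifts that encode the three morphologies (Group I PB
central bands on the PB edges; Groups II/III capsule sites exactly 2 mm
anterior/posterior of the medial epicondyle tip, 4 mm spread; Group III AB
bands shifted toward the common tendons, PCT behaving like an anterior
structure). Seed-to-seed variation enters through the head cloud only;
`perturb_specimen` adds seeded Gaussian noise to the attachment points for
digitization-sensitivity studies (under 0.23 mm noise the per-fiber/pose
strain changes are centered on zero with sd up to ~2.6 percentage points
for the shortest fibers).

The base layout was shaped once, by construction, so that the default
specimens reproduce the qualitative behavior expected of the medial elbow:
anterior structures (ACT, AB bands) taut in extension and tauter at 10°
valgus at every flexion angle; PCT taut with flexion in Group I; nine-fiber
average strain at 10° valgus decreasing from full extension to the flexed
reference in all groups. It was then frozen — it is not fitted to any
measured dataset, and no generator setting can be claimed to reproduce any
particular cadaver's strain values. Passing tests therefore demonstrate
correctness of the geometry pipeline and the plausibility of the layout's
patterns, not agreement with real tissue.

## Numerical choices

* Angles in degrees, coordinates in mm, strains in percent throughout.
* Unit-norm and orthogonality tolerances 1e-9; collinearity rejected at a
  relative cross-product norm of 1e-8; sphere-fit degeneracy at condition
  number 1e8.
* Landmark files store 3 decimal places (1 µm — one order below digitizer
  precision), making write→read→write a byte-level fixed point.
* Wide tables round to 1 decimal for display; long CSV keeps full
  precision, and Average rows are computed before rounding (averaging
  rounded values differs in the last digit).
* Fibers are ordered canonically (ACT, PCT, AB1–3, PB1–4) and poses
  valgus-major, flexion ascending, in every output.

## Problem sizes used in the shipped checks

Tests and the acceptance script run entirely on synthetic data at the
study's own scale: 40-point clouds, 9 fibers, 5 × 2 pose grids, cohorts of
up to 100 seeds per group, and 1000-draw Monte-Carlo loops for the sphere
fit — a few seconds end to end on one core.

## Known limitations

* Strain magnitudes depend on the axis-origin convention (above); only
  patterns, not absolute values, should be compared across conventions.
* Group labels are declared metadata. The macroscopic dissection that
  defines the morphology groups has no computational analogue here, so the
  package never infers a group from geometry.
* The generator emulates digitization geometry and noise, not population
  shape variation; cohort sweeps explore measurement noise and seeds, not
  anatomy distributions.
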