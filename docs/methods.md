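# Methods

## Scope and model

`avistereo` models a modular, tower-mounted bird protection system: up
to `N` identical camera modules share the 360° horizon (so each needs a
horizontal field of at least `360/N` degrees), and each module carries a
vertical stereo pair whose baseline is tilted back by half the field of
view so the cameras watch the space in front of the rotor.  All optics
are ideal pinhole relations — no lens distortion, no intrinsic
calibration, no epipolar rectification.  Disparity is measured along a
single baseline-aligned image axis on 1-based pixel rows, oriented so
that `y_u − y_d ≥ 1` for any object in front of the rig; pairs below
that floor are rejected as physically impossible (typically insects
close to one lens).

The geometry is deliberately the exact-inverse pair used throughout the
package: `stereo.solve_observation(D, H)` returns the continuous image
rows from which `stereo.localize` recovers `(Db, D, H)` to machine
precision.  The synthetic-scene generator projects through the same
equations, which makes every rendered scene an analytic oracle for the
measurement chain.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| baseline `B` | 1.0 | m | mounting convenience on the tower; larger baselines reduce ΔDb proportionally |
| axis resolution `VSR` | 3280 | px | long axis of the reference sensor, mounted along the baseline |
| axis field of view | 63.0 | deg | the horizontal FoV of the reference sensor/3 mm lens, used vertically by the rotated mounting |
| tilt `α` | FoV/2 | deg | by construction of the mounting; independently configurable |
| rig constant `B·VSR/(2 tan(FoV/2))` | 2676.2 | m·px | `Db · ydiff`; the single calibration constant of the rig |
| min object size | 12 × 2 | px | rule-of-thumb detectability floor; below it contours are treated as artefacts |
| false-pair filter | 150 | px | maximum centre offset between cameras; larger offsets are near-field clutter |
| class boundaries | see config | m, m² | wingspan 0.68/1.26/>1.50, height 0.32/0.40/>0.55, area 0.11/0.25/>0.41; half-open `[lo, next_lo)` intervals bridge the printed gaps |
| action policy | deterrents ≤ 300 m (all classes), stop ≤ 200 m (large) | m | illustrative defaults; the policy is entirely configuration-driven and a turbine stop always implies the deterrents |

The field-of-view requirement `FoVv ≥ 90° − arctan(E/R_B)` evaluates to
63.43° for a 40 m dead zone and an 80 m rotor; following engineering
practice the bound is floored to 63°, which the reference pair meets at
63.0°.  Because the sensor is mounted rotated, the *larger* sensor axis
must clear the vertical bound and the smaller one the 36° horizontal
bound; the feasibility flag of the selection table evaluates it that
way.

Wingspan and body height both convert pixels to metres with the
horizontal sensor ratio `VSS_h/(f·VSR_h)`; the reference sensor's pixels
are square to 0.2%, and a config flag switches to per-axis ratios for
sensors where they are not.

## Detection defaults

The detection stage has no canonical constants, so they live in the
config with these defaults: pre-blur 5×5, σ = 1.5 (suppresses sensor
noise and small lighting changes); difference threshold 25 of 255; ghost
merge blur 9×9, σ = 2.0; binary threshold 100.  The merge stage closes
the small gap between the two "ghosts" a moving object leaves in a frame
difference.  Its σ/threshold pair trades gap-bridging against thin-object
survival: a merge strong enough to fuse ghosts 10 px apart at a 127
threshold would erase targets thinner than ~5 px — and a large bird at
300 m is only 4.5 px thick — so the default keeps thin targets and
bridges small gaps, and wider gaps are handled by raising `merge_kernel`
/ lowering `binary_thresh` per deployment.  Contours are 8-connected
external boundaries; interior holes are ignored (birds are filled
silhouettes).  The enclosed area `o_s` is the shoelace (Green-formula)
area of the contour polygon.

## The classifier

The bird/non-bird network (conv 32 → pool → conv 32 → pool → dense 128 →
softmax 2, 3×3 kernels, 2×2 max pooling, ReLU, cross-entropy under Adam
with ε = 1e-7) is implemented directly in numpy via im2col/GEMM; with a
single-threaded BLAS a 2,000-crop, 10-epoch training run takes a few
minutes.  Pixel intensities are scaled to [0, 1]; label 1 is *bird*; the
decision threshold is 0.5.  Max-pool ties share the gradient evenly — a
valid subgradient that keeps training deterministic under a fixed seed.
The configured defaults (learning rate 1e-5, 50 epochs, 10% validation
split) describe a production-scale run over tens of thousands of crops;
the synthetic-data runs in the tests use the standard Adam rate of 1e-3
for 10 epochs, since at ~300 optimizer steps the production rate cannot
move a freshly initialized network appreciably.

## The synthetic scenes

The generator emulates two validation campaigns: static painted
silhouettes (small 0.8 × 0.3 m, medium 1.2 × 0.4 m, large 1.5 × 0.5 m)
at 50–300 m reference distances, and a circular drone-style orbit
(radius 143.3 m, height 102.9 m, 15 m/s, Gaussian position jitter of
σ = 2.5 m radial / 1.5 m vertical emulating GPS scatter).

Birds are rendered as filled isosceles triangles — base = wingspan,
height = body height, the same shape the area approximation
`O_approx = P_W·P_H/2` assumes — oriented perpendicular to the optical
axis as in gliding flight, with sub-pixel edge coverage (4× local
supersampling) standing in for optical anti-aliasing.  Between
consecutive frames a target translates ~3 px along the baseline axis
*and* flips wing posture (apex-up ↔ apex-down): a rigid translated
triangle's frame difference is two disconnected stripes that no sensible
merge kernel would fuse without destroying thin targets, whereas the
posture flip — a crude wing-beat — makes the difference cover the whole
silhouette footprint, as it does for real birds.

What the scenes do **not** emulate: plumage texture, weather and
illumination, wing-beat kinematics beyond the two-posture flip, flocks,
camera vibration, or rolling-shutter effects.  Passing tests therefore
demonstrate that the geometry, the measurement chain and the decision
logic are implemented correctly — not that the detector or classifier
would reach the same operating point on field data.  Non-bird crops
(insect dots, aircraft streaks, faint cloud blobs) are parametric
shapes whose purpose is class structure for the classifier, not
realism; a trivial dark-area threshold already separates them at ≥ 80%,
and the network's ≥ 95% held-out accuracy should be read against that
floor.

Two properties of the triangle model are worth knowing.  First, its
wing tips taper to zero thickness, so blur and thresholding shave
~2–3 px off the measured width; targets whose nominal projection sits
within ~2 px of the 12 px floor (the medium silhouette at 250 m, the
large one at 300 m) drop just below it, one 50 m step short of their
nominal range — painted bird silhouettes with finite tip chord keep
those last steps.  Second, the mass centre of a triangle sits a sixth of
its height below the bounding-box centre; the offset is common to both
cameras and cancels in the disparity.

## Numerical choices and degenerate inputs

- Angles are degrees at every public interface; trigonometry is radians
  internally.  Unit conversions (mm ↔ m) are centralized in the optics
  module.
- Disparities below 1 px raise `InvalidDisparityError`; quantized
  expected disparities clamp to ≥ 1 px.
- The quantization half-widths are the first-order symmetric form of an
  asymmetric exact interval `[C/(q+½), C/(q−½)]`; near half-integer
  disparities the upper excursion exceeds the symmetric bound by up to
  `ΔDb/(2q−1)`.  Sub-pixel (image-moment) disparity measurements sit
  well inside the bound; fully quantized ones can graze it.  The
  end-to-end campaign check accordingly allows one disparity quantum,
  while the sub-pixel round trip holds the strict half-quantum bound
  over a thousand random positions.
- Greedy ascending-distance matching is the contract for cross-camera
  pairing (ties broken by index order); it is *not* a globally optimal
  assignment, and the tests pin the greedy semantics.
- Object pairing averages the two cameras' pixel extents before size
  conversion.
- Class intervals are half-open `[lo, next_lo)`; values above the top
  boundary are `large`, values below every small bound are
  `uncategorized` and trigger nothing.
- Timestamp synchronization pairs instants greedily by smallest offset
  within a 50 ms tolerance; unmatched instants are dropped.

## Problem sizes used by the test suite

The silhouette campaign renders 18 full-resolution (3280 × 2464) stereo
scenes once per session; the round-trip bound check samples 1,000
random positions at the rasterized-silhouette level; the classifier
check trains on 2,000 crops for 10 epochs; the drone orbit uses 80
samples over 40 s at 2 Hz.  These sizes exercise every code path while
keeping a full run of the suite in the minutes range.

## Known limitations

- No multi-frame tracking, Kalman/PHD/MHT filtering, or flight-path
  prediction; every frame pair is processed independently.
- No background modelling: a bird hovering perfectly still between two
  frames is invisible to the detector.
- The decision stage assumes at most one detection per object per
  camera; overlapping birds in a flock will be fused or mismatched.
- Species-level identification is out of scope; the classifier is
  strictly bird/non-bird.
- Hardware actuation (lamps, speakers, turbine PLC) is represented only
  as the action set recorded in the event archive.
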