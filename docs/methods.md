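# Methods

## Model and assumptions

The limb is a rooted open chain (a tree) of rigid segments connected by
ideal hinge joints. Each joint's centre and axis are fixed in the parent
body's frame; for an ideal hinge the centre lies on the axis, so whether
the centre is regarded as stationary in the parent or in the child frame
is immaterial — both give the same world-frame centre at every pose, and
the test suite verifies this. At the reference (all-zero-angle) pose every
body frame coincides with the world frame, so body-local coordinates
double as reference-pose world coordinates. Rotating a joint by θ
(degrees at every public interface, radians internally) rotates the
entire distal subtree about the joint's world axis through its world
centre, right-hand rule. Joint-angle limits are enforced by default and
can be overridden per call.

Muscles are polylines of attachment points, ordered origin (proximal) to
insertion (distal), each stationary in its bone's frame. There is no
muscle wrapping, no curved path, no attachment area, and no bone-collision
checking: via points are the only mechanism for routing a path, which is
how the modelled system represents muscle geometry. A muscle crossing a
joint with more than one consecutive attachment pair is rejected rather
than given summed semantics — the single-free-segment formula below does
not cover that case. Broad muscles are expected to be modelled as several
independent one-line paths.

## The signed moment arm

About a joint with world centre **c** and unit axis **ĵ**, the free
segment's endpoints are re-expressed relative to **c**, projected onto
the plane through **c** normal to **ĵ**, and the signed arm is

r = p_proj,1 · (p_f × ĵ)/‖p_f × ĵ‖,  p_f = p_proj,2 − p_proj,1.

Two conventions had to be fixed that the formula alone does not fix:

* **Origin of the projection.** The projection plane must pass through
  the joint centre for r to be a joint moment arm, so all points are
  taken joint-centred before projecting. The axis is unit-normalised
  first, which makes the formula independent of the stored axis norm.
* **Which endpoint is p_proj,1.** The proximal (origin-side) endpoint.
  Swapping endpoints flips the sign of r. With this ordering and
  right-hand rotation the algebraic identity dL/dθ = p_proj,1 · (p_f ×
  ĵ)/L holds for the free segment's length L, so for a segment lying in
  the joint plane (‖p_f‖ = L) the signed arm satisfies **r = +dL/dθ**:
  positive r means the muscle lengthens as θ increases, i.e. its tension
  produces torque toward negative θ. Users preferring the opposite
  convention can flip a joint's axis, which negates r exactly.

For a free segment oblique to the joint plane the geometric |r| exceeds
the effective (torque-per-unit-tension) arm by the factor L/‖p_f‖; the
projected-plane value is what this engine reports, matching the method it
implements.

Degeneracy: when ‖p_f × ĵ‖ < 1e-9 mm (projected segment of near-zero
length, e.g. a segment parallel to the axis) the arm is undefined and the
engine raises rather than returning a large unstable number. The
threshold is far below anatomical scales and above double-precision
noise.

### Independent oracles

* **Point-to-line distance**: |r| must equal the perpendicular distance
  from the joint centre to the projected line of action. The oracle
  minimises ‖c − (p₁ + t(p₂ − p₁))‖ over the scalar line parameter with a
  bounded scalar optimiser — deliberately no cross products, so it shares
  no code path with the formula. Agreement is ~1e-14 mm over 1000 random
  configurations.
* **Tendon excursion**: the classical identity equates the effective arm
  with −dL/dθ. Implemented as a central finite difference with h = 0.01°
  (small enough that the O(h²) truncation error is ~1e-7 mm at these
  scales, large enough to stay above cancellation noise). The engine's
  sign relation r = −(−dL/dθ) holds exactly for the parasagittal fixture
  muscles and is asserted across every muscle × spanned joint × 100
  stride times.

## Gait trajectories

Joint angles over a normalised stride (touch down at t = 0, lift off a
config-supplied marker in (0,1)) are sums of sines with an explicit
constant offset, θ(t) = offset + Σ aₖ sin(bₖ t + cₖ). The offset term is
there because joint angles have nonzero means and a pure sine sum would
otherwise emulate the mean with a spurious near-zero frequency. Two
fitting modes:

* **Periodic (default)**: bₖ = 2πk. The model is then linear in
  (offset, aₖ cos cₖ, aₖ sin cₖ) and is solved exactly by least squares —
  deterministic, no iteration, and the fitted curve closes into a loop at
  t = 1 by construction.
* **Free frequencies**: Levenberg–Marquardt refinement of all
  coefficients, deterministically initialised from the periodic solution.
  Available for fidelity to externally fitted curves; not the default
  because stepping analyses want exact loop closure.

Default term count is 4, enough for smooth mammalian gait curves while
requiring only 2·(2·4+1) = 18 samples; fits report their RMSE. On
noise-free harmonic data recovery is exact to ~1e-14°, and with 0.5°
additive noise at 200 samples the fitted curve stays well inside 0.5°
RMSE of the truth (measured ~0.06°).

## Profiles, surfaces, sensitivity

* Isolated sweeps hold all other joints at 0° by default (the standard
  convention for single-joint validation sweeps), overridable per run.
  The swept joint defaults to the measured joint but can differ, which
  probes adjacent-joint dependence directly and realises the
  rigid-co-rotation pulley fixture.
* Stepping profiles sample uniformly in stride time (default 100 samples
  per cycle), not uniformly in angle, since the step cycle is the object
  of interest. Every sample records all joint angles because a
  biarticular arm is a function of both spanned joints.
* Reachable surfaces evaluate r on a regular grid (default 1°) over the
  bounding box of the visited (θ₁, θ₂) pairs, masked to cells within 2
  grid cells of the visited trajectory — the off-trajectory part of the
  box is not physiologically reached and is left unevaluated. Grid poses
  hold non-spanned joints at zero; for a single-free-segment muscle the
  arm provably does not depend on them, so grid values coincide with
  stepping samples at coincident angles.
* Moment-arm-vs-length loops min-max normalise both quantities over the
  cycle; a constant-length muscle (zero range) is returned raw with a
  flag instead of dividing by the zero range.
* Sensitivity analysis displaces one free-segment endpoint by ±m mm
  (default 1 mm) along an explicit body-frame unit direction and
  recomputes the profile on the identical sweep. Directions are explicit
  vectors in config because anatomical descriptions ("cranially along the
  ischium") cannot be resolved by a geometric engine without bone
  surfaces. The frequently made observation that profiles respond most to
  the attachment nearest the joint is geometry-dependent and is reported
  as a diagnostic, never asserted.
* Femur-length normalisation divides r by a reference length (the
  rat-like fixture's femur is 35.75 mm); normalising twice is refused.

## The synthetic fixtures

No anatomical coordinate set ships with the package; the generator builds
three synthetic models with known behaviour, and all attachment geometry
is invented plausible proportion, never dissection data.

* **pulley**: a muscle spanning the distal joint of a two-joint linkage
  at perpendicular offset d while the proximal joint is swept. The
  spanned assembly co-rotates rigidly, so r ≡ d exactly — by rigid-motion
  invariance, not by wrapping. (A straight two-point segment rotating
  about its own hinge cannot hold a nonzero constant arm: setting the
  centre-to-chord distance constant in the rotation angle forces the
  trivial r = 0 case, which is why an idealised constant-radius pulley
  has no two-point polyline realisation.)
* **planar_two_body**: one hinge, endpoints (−a, d) fixed and (b, d)
  rotating; the signed arm has the closed form (x₁y₂ − y₁x₂)/‖P₂ − P₁‖ in
  the engine's orientation convention. Engine agreement is ~1e-15 mm.
* **rat_like**: pelvis–femur–tibia–foot with hinge hip/knee/ankle (femur
  35.75 mm, tibia 40 mm), one-plus monoarticular muscle per joint, two
  single-segment biarticular muscles (hip–knee and knee–ankle), a
  via-point biarticular muscle, and a periodic two-harmonic gait preset
  with distinct phases per joint (stance ≈ 60 % of the stride). Each
  muscle runs in its own parasagittal plane — a constant mediolateral
  offset, as real sagittal-plane hindlimb lines of action approximately
  do — which makes the projected arm coincide with the tendon-excursion
  arm exactly and keeps the two oracles comparable at tight tolerance.
  Attachments are jittered ±2 mm in-plane from a seeded generator;
  geometry is resampled if any free segment's ‖p_f × ĵ‖ falls below
  0.1 mm anywhere on a joint-limit grid. Identical seeds give
  byte-identical serialised models.

What passing tests on these fixtures do show: the vector formula, its
sign convention, the free-segment logic, the biarticular coupling
structure and the analysis machinery are correct, to tolerances of
1e-3 mm (finite-difference oracle) down to exact equality (invariances).
What they do not show: anything about a particular animal's moment arm
magnitudes — the fixture's arm ranges (roughly 1–16 mm) are plausible for
a rat-sized limb but are properties of invented geometry. Real limbs
additionally have migrating joint centres, muscle wrapping, out-of-plane
axes and broad attachment areas, all outside this engine's scope.

## Numerical choices

* Angles in degrees at every interface; radians only inside
  trigonometry. Lengths in mm throughout.
* Rotation matrices via axis-angle (scipy); transforms are homogeneous
  4×4, composed root-to-leaf once per pose.
* Degeneracy threshold 1e-9 mm on ‖p_f × ĵ‖; finite-difference step
  0.01°; fixture degeneracy guard 0.1 mm; point-line oracle bounded to
  |t| ≤ 1e6 with 1e-10 parameter tolerance.
* Isolated sweeps include both endpoints; a 60° range at 1° step yields
  61 samples.
* Verification problem sizes — 1000 random oracle configurations,
  100-point gait cycles, 61-point sweeps — were chosen so every check
  runs in seconds while sampling each degree of freedom densely.

## Known limitations

* Hinge joints only; no translating or migrating joint centres.
* One free segment per muscle–joint pair; paths crossing a joint twice
  are rejected.
* The projected arm of an out-of-plane segment is the geometric, not the
  effective, arm (factor L/‖p_f‖); the tendon-excursion oracle reports
  the effective one, and the two agree only for in-plane segments.
* No torque or force modelling; moment arms are the endpoint.
* Abduction/adduction and internal/external rotation axes are not
  analysed; the engine is axis-agnostic but the fixtures are sagittal.
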