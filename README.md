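# momentarms

Signed muscle moment arms in hinge-jointed musculoskeletal limb models.

`momentarms` is for biomechanists and neuromechanical modellers who
represent a limb — typically a rodent hindlimb — as rigid bone segments
connected by hinge joints, with muscles as polylines of bone-fixed
attachment points, and who need the signed moment arm of each muscle about
each joint it crosses: in isolated-joint sweeps, and over a physiological
step cycle where the moment arm of a *biarticular* muscle depends on the
configuration of both joints it spans.

## The method

A muscle's path is an ordered polyline of attachment points, origin
(proximal) to insertion (distal), each stationary in its bone's local
frame. Because attachments are bone-fixed, only the **free segment** — the
single consecutive attachment pair whose endpoints lie on opposite sides
of a joint — changes length as that joint rotates, and it alone determines
the moment arm.

For a hinge with world-frame centre **c** and unit axis **ĵ**, the two
free-segment endpoints **p**₁ (proximal), **p**₂ (distal) are re-expressed
relative to **c** and projected onto the joint plane:

```
p_proj,i = p_i − (p_i · ĵ) ĵ                (projection onto the joint plane)
p_f      = p_proj,2 − p_proj,1              (projected free segment)
r        = p_proj,1 · (p_f × ĵ) / ‖p_f × ĵ‖  (signed scalar moment arm, mm)
```

|r| is the perpendicular distance from the joint centre to the projected
line of action. With proximal-first ordering and right-hand-rule joint
rotation, r = +dL/dθ for free segments lying in the joint plane: positive
r marks a muscle that lengthens as the joint angle increases. Two
independent oracles verify the formula — a brute-force point-to-line
distance minimisation (magnitude) and the classical tendon-excursion
identity −dL/dθ (magnitude and sign).

Joint-angle trajectories over a normalised stride (touch down at t = 0)
are modelled as sums of sines, θ(t) = offset + Σₖ aₖ sin(bₖ t + cₖ), with
stride-harmonic frequencies by default so stepping profiles close into
loops.

## Worked example

```python
from momentarms import (FixtureSpec, generate_fixture, stepping_profile,
                        normalize_profile, moment_arm, pose_at)

fix = generate_fixture(FixtureSpec("rat_like", seed=7))   # synthetic hindlimb
ham = fix.muscle("hamstring")                             # spans hip and knee

for joint in ("hip", "knee"):
    prof = stepping_profile(fix.chain, ham, joint, fix.trajectories, n_samples=100)
    norm = normalize_profile(prof, femur_length=35.75)
    print(f"hamstring about {joint}: r in [{prof.r.min():.2f}, {prof.r.max():.2f}] mm "
          f"(femur-normalized [{norm.r.min():.3f}, {norm.r.max():.3f}])")
```

prints

```
hamstring about hip: r in [12.43, 13.67] mm (femur-normalized [0.348, 0.382])
hamstring about knee: r in [7.26, 9.78] mm (femur-normalized [0.203, 0.273])
```

the hamstring's moment arm about each spanned joint over one stride, raw
and divided by the model's femur length for size-independent comparison.
The biarticular dependence is visible when the same knee angle recurs at
two stride times with the hip in different configurations:

```python
from scipy.optimize import brentq
knee = fix.trajectories["knee"]
t1 = 0.20
t2 = brentq(lambda t: knee(t) - knee(t1), 0.45, 0.95)    # same knee angle again
rec = fix.muscle("rectus")
r1 = moment_arm(rec, pose_at(fix.chain, fix.trajectories, t1), fix.chain, "knee")
r2 = moment_arm(rec, pose_at(fix.chain, fix.trajectories, t2), fix.chain, "knee")
print(f"knee at {knee(t1):.1f} deg twice: r = {r1:.3f} vs {r2:.3f} mm")
```

```
knee at -24.2 deg twice: r = -1.082 vs -0.871 mm
```

— a 19 % difference at the identical knee angle, so an angle-indexed lookup
table is ambiguous for biarticular muscles: both joint angles are needed.

The same operations are available from the shell:

```sh
momentarms fixture generate --kind rat_like --seed 7 \
    --out model.json --gait gait.csv --trajectories coeffs.json
momentarms model validate --model model.json
momentarms profile stepping --model model.json --trajectories coeffs.json \
    --muscle hamstring --joint knee --out profile.csv
momentarms sensitivity --model model.json --muscle hamstring --joint knee \
    --attachment proximal --direction 0,1,0 --sweep-min -30 --sweep-max 15 \
    --out sensitivity.csv
```

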