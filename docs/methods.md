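# Methods

## The control problem

A light-gated expression system in a marked site on a freely moving mouse
must receive a defined blue-light dose. The rig that does this consists of
an overhead camera watching the cage floor, a two-axis (pan/tilt) gimbal
carrying a laser diode above the cage, and software that finds the marked
site in each frame and keeps the beam on it while an illumination schedule
runs. This package implements that software and a synthetic scene that
stands in for the camera so the whole loop can be exercised and measured
without hardware.

## Scene model and synthetic data

The scene generator emulates what the tracker actually consumes: a dark,
uniform cage floor (20 × 20 cm, default 640 × 640 px ⇒ 32 px/cm), a grey
elliptical body (default semi-axes 120 × 56 px ≈ 7.5 × 3.5 cm, oriented
along the velocity), a saturated red disk riding on it (default radius
24 px ≈ 0.75 cm — a pen-drawn circle ~1.5 cm across), additive Gaussian
sensor noise (default σ = 3 grey levels, a modest webcam), and scripted
occlusion intervals during which the marker is simply not drawn (the animal
rearing or grooming over the mark). Rasterisation uses
pixel-centre-in-shape membership with pixel centres at integer coordinates
(origin top-left, u rightward, v downward), and the ground truth stores the
exact sub-pixel projection of the marker centre, so tracking error is
measured against an exact reference.

It does **not** emulate fur texture, shadows, lens distortion, lighting
gradients, partial marker visibility, or multiple animals. Passing tests
therefore demonstrate the pipeline's correctness and its robustness to
pixel noise and full occlusion — not performance on arbitrary real footage,
where colour thresholds would need tuning per setup.

**Motion.** The animals move freely and no canonical motion model exists
for cage-scale locomotion, so the generator uses the standard bounded
stochastic choice: an
Ornstein–Uhlenbeck velocity (exact discretisation
v′ = e^(−dt/τ) v + s·√(1 − e^(−2dt/τ))·ξ) with reflective walls.
`speed_scale_m_per_s` is the stationary per-component velocity s.d.;
the default 0.05 m/s gives a mean speed of ≈ 6 cm/s, a realistic open-field
locomotion level, with τ = 1 s persistence and a 1 cm wall margin.

## Tracking pipeline

Per frame: (1) an HSV colour mask — hue in degrees, two windows
([0°, 15°] and [345°, 360°], saturation ≥ 0.4, value ≥ 0.2) to cover red's
hue wrap-around; (2) morphological opening with a disk element (default
radius 2 px) to delete noise speckle, with out-of-image pixels counted as
background; (3) 8-connected components, each summarised by its pixel count
and the arithmetic mean of its member pixel coordinates. Blob ordering and
selection are totally ordered (size desc, then centroid v, then u; nearest
blob within `max_jump_px` of the last fix wins when history exists) so runs
are bit-reproducible. The reported position is an exponential moving
average (default α = 0.5 — one-frame effective lag against sub-pixel
jitter suppression); when the marker vanishes, the last smoothed position
is held for `hold_frames` (default 15 ≈ 0.75 s at 20 fps) and then reported
absent, which also gates the laser off.

The HSV conversion is the standard hexagonal formula computed in float64
(documented in `rgb_to_hsv_deg`); it is checked bit-for-bit against an
independent per-pixel oracle and against `colorsys` in the tests.

## Pointing geometry

A fixed overhead camera viewing a planar floor is exactly a homography, so
no full intrinsic/extrinsic model is fitted; calibration is the normalised
direct linear transform (least squares beyond 4 points), and lens
distortion is out of scope. Gimbal pointing is closed-form: tilt =
atan(d/h) from nadir, pan = bearing of the target from the yaw-reference
axis (the direction the encoder was zeroed against, parallel to the
mounting frame), reported in (−180°, 180°]. Directly beneath the mount the
bearing is undefined and the previous pan is kept. Targets outside the
axis limits are clamped and flagged rather than rejected, since a moving
animal may transiently leave the reachable cone. The marked site is
treated as lying on the floor plane; the animal's back height adds a
roughly constant offset much smaller than the beam footprint and is
ignored.

**Mount placement.** The default gimbal position is a top corner of the
gantry frame, (0.205, 0.205, 0.33) m. An early design placed it near the
arena centre, which is where the animal spends most of its time — and a
pan/tilt head pointed at targets crossing its nadir suffers the keyhole
singularity: the pan demand flips by up to 180° in one frame, which no
finite slew rate can follow, producing multi-centimetre pointing excursions
on every crossing. Mounting at the frame corner keeps the entire floor
inside a smooth ~90° pan range and bounded pan rates (< 200°/s at the
default motion level), which is the standard engineering resolution of this
singularity.

## Servo and schedule

The real gimbal runs an auto-tuned PID controller whose gains are not
published; what matters for pointing performance is bounded angular
velocity, so the servo is abstracted as a slew-rate limit (default
300°/s per axis, independent axes, target reached exactly when within one
step). The loop acts on the centroid of the current frame — one frame of
latency at spot time, a conservative no-prediction policy.

Schedules are continuous-on, off, or an on/off cycle (hours), evaluated
with half-open light intervals. Dose is irradiance × on-time with on-time
computed by exact interval arithmetic, so whole cycles are exact and the
dose is additive over any split. `Schedule.time_scale` maps simulation
seconds to schedule seconds so that day-length cycles can be exercised in
seconds-long desk runs. The laser is on only when the schedule says on
*and* the tracker currently has a target (including the hold window);
this safety gate is asserted over every frame of every simulated run.

## Metrics and problem sizes

`on_target_fraction` counts laser-on, non-occluded frames whose beam spot
lies within the physical marker radius of the true marker centre;
pointing-error statistics are over the same frames (reported as 0 when no
frame qualifies, e.g. under a dark schedule). The headline closed-loop run
is 60 s at 20 fps with the default motion level; it and the accuracy runs
use scenes of 640, 320 and 256 px across the 20 cm floor — identical
physical dimensions at coarser pixel pitch, a problem size chosen so the
full suite and the acceptance script run in minutes on one CPU. The
regression bound (on-target ≥ 0.95) was frozen from the implementation's
own seeded runs (observed 0.98–0.99 across seeds).

## Numerical choices and degenerate inputs

* Colour bounds are inclusive on both ends; mask equality against the
  brute-force oracle is exact, not approximate.
* Opening with radius 0 is the identity; an isolated pixel dies at
  radius 1. Anti-extensivity and idempotence hold for all radii.
* Homographies are normalised to h₃₃ = 1; calibration raises on rank
  deficiency (e.g. collinear points) and on h₃₃ ≈ 0; projective application
  raises when a point maps to the plane at infinity.
* Zero motion scale with zero initial velocity leaves the position fixed
  (used as the stationary-target case).
* Reflection at walls folds position and flips velocity; positions can
  never leave the margin-inset arena.
* All randomness flows from one seeded generator per run (motion and noise
  share a stream in frame order), so frames, logs and CSVs are
  byte-reproducible.

## Known limitations

* Single animal, single marker, single gimbal; four-cage operation is four
  independent loops, not modelled jointly.
* No beam-divergence or irradiance-profile physics: the "spot" is the ray's
  floor intersection point.
* Pan slews take the direct angular path without wrap-around, which is
  correct within the default mount's ~90° working range but would be
  suboptimal for a mount requiring ±180° sweeps.
* The colour mask assumes the marker is the only saturated red object in
  view; the blob-size and jump gates mitigate but cannot eliminate
  confusers of similar colour and scale.
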