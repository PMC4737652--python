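# Methods

This note documents the models, conventions, and numerical choices
behind `flightmaneuvers`, and what the synthetic validation does and
does not demonstrate.

## Scope and data model

The package analyzes 200 Hz 3D tracking output for free-flying birds:
per frame, a body position (m) and a body-axis unit vector whose sign
is ambiguous (image-based axis estimates cannot tell head from tail).
Coordinates are right-handed with z up. A *trajectory* is one
continuously tracked object; gaps in the frame sequence split a
trajectory rather than being interpolated, because the upstream tracker
itself terminates objects when it loses them.

## Smoothing

Positions and axis vectors are smoothed with a forward Kalman filter
followed by the backward (Rauch–Tung–Striebel) recursion under a
discrete constant-velocity model with step `T = 1/fps`. The process
covariance per axis is the continuous-white-noise-acceleration block
`sigma2·[[T³/3, T²/2],[T²/2, T]]` with `sigma2 = 0.01` (m²/s³ for
position); observation covariances default to `R_pos = 1.44e-4 m²`
(12 mm RMS) per axis for position and `R_ori = 1.44e-6` for the axis
vector. The filter is seeded with the first observation, zero velocity,
and a diagonal initial covariance of 1.0; the backward pass starts from
the final filtered state. The implementation is verified against the
equivalent batch MAP (banded least-squares) solution of the same
state-space problem to ~1e-10.

Two properties of this smoother matter for interpretation:

* **Transient overshoot.** On data whose true acceleration is constant
  (e.g. a falling object), the smoothed acceleration is exactly g in
  steady state, but each trajectory end contributes a deterministic
  transient that first suppresses and then overshoots the true
  curvature by a few percent, settling over roughly 0.5–0.8 s. The
  "peak acceleration" of a short smoothed drop therefore depends
  strongly on trace duration (about 8 m/s² at 0.5 s through 10.4 m/s²
  at 1 s for g = 9.81). The calibration fixture uses seven drops with
  durations evenly spanning 0.5–1.0 s.
* **Feature distortion.** Smoothing attenuates high-curvature content:
  a 0.6 m circular arc flown at 1.5 m/s comes out ~3 % smaller in
  radius, and sharp acceleration onsets ring by several percent. These
  biases are properties of the published smoothing constants, not of the
  estimators; the arc-radius estimator reproduces the radius of the
  *smoothed* path to 0.1 %.

### Head/tail resolution

After smoothing (axis vectors are first flipped frame-to-frame into a
common hemisphere, which is pure continuity bookkeeping), the head end
is chosen per frame by maximizing a cumulative alignment score: with
weight `Speed` (the speed in m/s when above 0.5, else 0.5), the cosine
with the velocity tipped 15° toward vertical; and with weight
`1 − Speed` each, the cosine with vertical and with the previous signed
axis. The first frame omits the continuity term. The sign chain is
optimized exactly by a two-state Viterbi recursion (a greedy
left-to-right pass is available as an option); tests verify exact
agreement with brute-force enumeration over all `2^n` chains.

Taken literally, the weighting lets `Speed` exceed 1 above 1 m/s, which
makes the posture and continuity weights negative — and a negative
continuity weight *rewards* flipping the axis on every frame of fast
upright flight. Any resolver honoring that score (sequential or exact)
then produces alternating head/tail assignments above roughly 2 m/s,
which corrupts every angular kinematic downstream. The default
therefore clamps the speed weight into [0, 1]
(`cap_speed_weight=True`): below 1 m/s nothing changes, and above it the
travel term simply dominates, which is the evident intent of the
weighting. The literal weighting remains available behind the flag, and
a regression test documents its degeneracy.

## Kinematics

Velocity and acceleration are first and second derivatives of an
interpolating cubic spline (zero smoothing — the Kalman stage already
denoises) through the smoothed positions. The body axis is expressed as
azimuth (`atan2(o_y, o_x)`, unwrapped before differentiation) and global
pitch (`asin(o_z)`, in [−90°, 90°]); body roll is unobservable from an
axis vector. Heading is the direction of the horizontal velocity,
unwrapped, and undefined below 1 cm/s of horizontal speed; undefined
frames are excluded from the unwrap chain and derivative spline.
"Distance" always means cumulative path length (the vertical distance is
the path length of the z component); a config switch selects net
displacement instead.

Extrema are found with a hysteresis walk: an extremum is confirmed once
the series moves away from it by more than a swing threshold (default
0.05 m/s for speed series), plateaus report their midpoint, and segment
endpoints count as boundary extrema so maneuvers truncated by trajectory
ends remain bounded. Sub-threshold drift is treated as constant.

## Maneuver detection

Ten stereotyped classes are searched independently (overlap allowed):

| class | bounds | constraints | metric |
|---|---|---|---|
| accel3D | total-speed min → max | xyz path > 25 cm | max speed |
| accelHor / decelHor | horizontal-speed min→max / max→min | xy path > 25 cm, z path < 10 cm | max tangential accel (m/s²) |
| accelVU / accelVD | vertical-velocity min→max / max→min | z path > 25 cm | max vertical accel |
| pitchUp / pitchDown | pitch-velocity sign runs | Δpitch > 45°, xyz path < 10 cm | Δpitch/duration (rev/s) |
| yawTurn | azimuth-velocity sign runs | Δazimuth > 90°, max pitch < 75°, xyz path < 10 cm | Δazimuth/duration (rev/s) |
| arcingTurn | heading-velocity > 90°/s runs | min speed_xy > 0.5 m/s, xy path > 25 cm, z path < 10 cm | mean speed, radius, centripetal accel over a 25 cm clip |
| pitchRollTurn | consecutive total-speed maxima | max pitch > 75°, ≥ 12.5 cm of path each side of the speed minimum, clip z path < 10 cm | clip duration, heading change over clip |

Conventions worth spelling out:

* Horizontal acceleration metrics use the derivative of horizontal
  *speed* (tangential acceleration), excluding the centripetal
  component; the magnitude-of-acceleration alternative is a switch.
* The 25 cm clip of a complex turn is the smallest frame window whose
  path length reaches 25 cm, split as evenly as the sampling allows
  around the sharpest point (maximum |heading velocity| for arcing
  turns; the speed minimum for pitch-roll turns). If either side cannot
  supply 12.5 cm of path the maneuver is rejected — for pitch-roll
  turns we read the printed one-sided constraint as requiring at least
  12.5 cm on *both* sides, since the centered clip is otherwise
  impossible.
* The arc radius is the clip's measured path length divided by its
  heading change in radians (on a perfect circle this recovers the
  radius to ~1e-5 despite integer-frame clipping), and the centripetal
  acceleration is definitionally `Arc_vel_avg² / Arc_rad`.
* The pitch-roll heading change (`PRT_deg`) is measured between the
  clip's entry and exit frames; an azimuth-based variant is a switch.
* Rotational runs are bounded where the angular velocity leaves a dead
  band. The default band is 5 °/s, raised automatically to four times
  the robust (MAD) noise scale of the angular-velocity series; each
  bound is extended one frame outward when the adjacent frame still
  continues the sweep, which places the bound on the angle extremum
  itself. For Kalman-smoothed input, `DetectionParams.for_smoothed()`
  raises the band to 50 °/s: smoothing spreads low-velocity tails well
  beyond a rotation's true bounds, and on scripted fixtures the 50 °/s
  crossing best recovers the true rotation duration (hummingbird
  rotations peak far above this, so no real maneuver is lost).
* Arcing and pitch-roll turns are mutually exclusive by construction
  (one requires > 0.5 m/s throughout, the other brakes to near zero);
  this is asserted in tests rather than enforced.

`PRT%` is the per-trial fraction of complex turns executed as pitch-roll
turns, undefined (missing) when a trial has neither class.

## Statistics

Metric values are pooled per metric and trimmed at 5 SDs from the
pooled mean (single pass) before averaging to one record per bird-trial
(the study design gives 52 records: 20 solo and 16 paired competition
trials for 20 birds across three experiments).

**Repeatability.** For each metric, an intercept-only linear mixed
model with a bird random intercept is fit by REML; ICC is the
among-individual variance over the total. The one-random-intercept
model admits a profiled REML criterion in the single variance ratio, so
the fit is an exact bounded 1-D optimization — no general mixed-model
optimizer that can stall, and fast enough for the 5000-iteration
parametric bootstrap used for percentile confidence intervals
(simulate new bird intercepts and residuals from the fitted model,
refit, take 2.5/97.5 percentiles). The fit agrees with `lme4::lmer` to
six decimals and is cross-checked against `statsmodels.MixedLM` in the
test suite. Classification: high > 0.70, moderate 0.40–0.70, low
< 0.40, "not repeatable" when the CI reaches zero.

**Burst muscle capacity.** Load lifted is regressed (OLS) on wing
aspect ratio plus capture-site indicators; the residual is the burst
measure used downstream. Aspect ratio is `4·L²/S` with single-wing
length and area.

**Multimodel inference.** Eight candidate fixed-effect structures are
fit per metric — wing size, wing shape, size+shape, burst, burst+size,
burst+shape, burst+size+shape, and intercept-only — all with a bird
random intercept; the non-null models also carry competitor presence,
experiment (3 levels), and body mass, plus days post-capture for the
five metrics affected by time in captivity (Vel_max, AccHor_max,
DecHor_max, Arc_vel_avg, Arc_cent_max). Fits use full maximum
likelihood (the same profiled 1-D reduction, verified against lme4 and
statsmodels), compared by AICc with `k` = fixed effects + 2 variance
parameters. Models within 2 AICc of the best form the support set;
coefficients are averaged conditionally (over supported models
containing them) with renormalized Akaike weights, and CIs use the
unconditional variance (within-model plus between-model spread).
Relative importance is the summed renormalized weight of supported
models containing the predictor. Continuous predictors are z-scored, so
coefficients are standardized betas; categorical terms stay as
indicators. Marginal R² is the variance of fixed-effect predictions
over the total (fixed + random-intercept + residual) variance, with
experiment and days-post-capture coefficients zeroed before computing
the fixed-effect variance, so it reflects the effects of interest only.
PRT% is modeled as a Gaussian response like the other metrics. Grubbs
outlier screening (iterative, two-sided, α = 0.05) is provided for
heavy-tailed metrics such as the pitch-roll heading change.

## Synthetic data

The generator exists so every stage can be validated against known
truth without the original tracking data.

* **Free fall**: `z(t) = z0 − g t²/2` (g = 9.81; the 9.8 calibration
  figure is 2-significant-figure rounding) plus isotropic Gaussian
  noise of SD 12 mm, seven traces spanning 0.5–1.0 s.
* **Bouts** are composed from kinematic primitives driven by piecewise
  profiles of horizontal speed, heading, vertical velocity, and body
  angles. Linear ramps (constant acceleration) get C1 smoothstep corner
  blending — default window 0.05 s at joins, widened to 0.10–0.15 s at
  planted acceleration onsets so the acceleration is trapezoidal rather
  than step-like (steps excite smoother ringing that contaminates peak
  readings) — the blend preserves knot values and never exceeds the
  adjoining slopes, so closed-form peak accelerations stay exact. Angle
  sweeps use smoothstep ramps whose average velocity is exactly
  Δangle/duration. The five standard bouts plant all ten classes at
  magnitudes matching the published descriptive statistics (horizontal
  accelerations ≈ 5.5 m/s², vertical ≈ 3.8 m/s², arcs of 0.6 m radius
  at 1.5 m/s, pitch-roll turns braking at 3 m/s² with a 0.25 s dwell at
  the turn point). Rotations ride on a slow 8 cm/s drift: real hovering
  birds are never perfectly stationary, and a real travel direction
  anchors head/tail resolution without violating the 10 cm in-place
  limit. Ground truth is recorded by the primitives themselves
  (closed forms) plus a finalization scan of the composed speed profile
  for the total-speed accelerations; clip-based pitch-roll timings are
  evaluated on the frame grid with the same at-least-half-path rule the
  detector uses, so truth carries the same frame quantization.
  Tracking noise is isotropic Gaussian position error (12 mm), small
  Gaussian perturbation of the axis vector (SD 0.0012 per component,
  matching the orientation observation variance), and Bernoulli sign
  flips (p = 0.5) of the axis.
* **Population records** are drawn from the linear mixed model the
  analysis assumes: per metric, a grand mean (published descriptive
  values), a bird random intercept whose SD defaults to a quarter of
  the published range of bird means, a residual SD set from the target
  ICC, and optional fixed effects on centered predictors. Traits are
  drawn inside the published morphological ranges with aspect ratio,
  area, and length kept consistent, and load lifted declining mildly
  with aspect ratio. The trial design reproduces the study's 52
  bird-trial records.

**What the validation shows and does not show.** On noise-free bouts
the detector recovers every planted maneuver with no false positives
and metric errors below 1 %; under full tracking noise and smoothing,
mean per-metric errors stay below 5 %. Individual noisy instances can
err by up to ~8 % where smoother ringing interferes constructively, and
the arc-radius bias (~4–5 %) is deterministic shrinkage by the
smoother. Real flight is not piecewise-scripted: real maneuvers overlap
irregularly, accelerations are not trapezoidal, and orientation noise is
not isotropic, so these figures bound clean-signal fidelity, not field
accuracy. The population generator realizes exactly the model the
statistics assume; recovery tests therefore validate the estimators,
not the model's adequacy for real birds.

## Problem sizes used in the validation suite

The test suite and acceptance script keep simulations at sizes chosen
for tight, fast feedback: seven free-fall traces; five standard bouts
across six noise seeds; 200 generative replicates per true ICC level;
100 replicates for model-selection recovery (500 bootstrap iterations
where CIs are needed, versus the 5000 default in production use); and a
full 20-bird pipeline run with 10 bootstrap iterations. All are
reproducible from fixed seeds.

## Known limitations

* Acceleration-magnitude metrics inherit a few percent of bias from the
  published smoothing constants (transient overshoot and feature
  attenuation); values are comparable within a study but not across
  different smoothing setups.
* Average rotational velocities depend on where the angular-velocity
  bounds are placed; after smoothing this is resolution-limited, hence
  the raised dead band for smoothed input.
* The intercept-only REML/ML machinery covers a single random
  intercept; crossed or nested random effects are out of scope.
* Identity assignment across close encounters, camera calibration, and
  image-based orientation estimation are upstream of this package.
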