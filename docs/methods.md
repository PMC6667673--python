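# Methods

This note documents the models, conventions, parameters and numerical
choices behind `gaitseg`, and what the synthetic evaluation does and does
not demonstrate.

## Sign convention and segment model

All kinematics live in the sagittal plane (x along the walking direction,
y up).  A segment is the proximal→distal vector; its angle is measured
from the downward vertical and is **positive when the distal end is
posterior** to the proximal end.  With this convention every segment's
angular velocity is positive during stance (the limb rotates forward over
the planted foot) and negative during swing, which is the sign structure
the detector exploits.  The convention is the package's own choice — any
convention that makes stance positive works; only the sign of the gyro
channel must match it.

Thigh and shank lengths are taken equal at 24.5 % of body height
(standard anthropometric tables).  The virtual leg is the direction of
`thigh_vec + shank_vec`; the extended leg of `2·thigh_vec + shank_vec`.
Both are computed from angles plus lengths (not raw marker sums) so the
marker-based and the IMU-based paths share one code path.  With equal
lengths the virtual-leg angle is exactly the mean of thigh and shank
angle whenever they differ by less than 180°; the uniform-scale
invariance of both compositions is property-tested.  An optimal
thigh:shank weighting is deliberately out of scope.

## Measurement paths

**Marker path.**  Hip/knee/ankle sagittal tracks at 200 Hz are linearly
upsampled to 1 kHz (the force-plate clock), low-pass filtered with a
zero-lag 4th-order 10 Hz Butterworth (forward–backward; "order" always
names the single-pass design order, so the cutoff attenuation is applied
twice), converted to angles, unwrapped, composed into the virtual
segments, and differentiated (central differences inside, one-sided at
the edges).

**IMU path.**  Per segment, a gyro (deg/s) and two accelerometer
components (g) at 133 Hz are fused by a scalar Kalman filter whose state
is the segment angle in degrees: predict by trapezoidal gyro integration
with process variance q = 5·10⁻⁵ deg² per step; correct toward
`atan2(anterior, axial)` with measurement variance r = 7 deg².  The
steady-state gain is ≈ 0.0027 per step — the filter is essentially a
gyro integrator whose drift is pinned by the accelerometer on a ~3 s
time scale.  Numerical choices that matter:

* *Trapezoidal integration.*  A rectangle rule shifts the integrated
  angle — and with it every zero crossing — by half a sample (≈ 0.36 % of
  a gait cycle at 133 Hz); the trapezoid removes that bias.
* *Self-starting.*  The initial angle defaults to the first accelerometer
  inclination and the initial variance to r, which makes the first
  updates behave like recursive averaging of the accelerometer (error
  decays ~1/n, below 0.1° within 5 s for a constant tilt).  Constant
  gyro bias b settles to a constant offset ≈ b·dt·(1−K)/K, not a drift.
* *Free-fall guard.*  Accelerometer samples with magnitude < 0.05 g carry
  no attitude information and hold the previous inclination.
* The filter state is the angle alone (one q, one r); there is no bias
  state and no magnetometer.

The detector consumes the **derivative of the composed virtual-segment
angle** in both paths, matching the reference processing, rather than an
analytic combination of segment velocities (the two agree to numerical
tolerance).

## Force-based reference

Heel-strike: each upward crossing of a 400 N trigger on the raw vertical
GRF starts a backward scan; the event is the first sample, going
backward, that is ≤ 0 N or that exceeds its successor while being below
10 N.  The "< 0 N" of the usual formulation is relaxed to "≤ 0 N"
because a noise-free force is exactly zero in swing and the scan would
otherwise never terminate.  One scan runs per contiguous supra-trigger
run; duplicate resolutions collapse.  Toe-off: on a zero-lag 2nd-order
20 Hz filtered copy, the first sample below 10 N starting 100 ms after
each heel-strike.  The 400 N trigger, 10 N floor and 100 ms blanking are
configurable (`GrfEventParams`) since the trigger is subject-dependent.
Strides pair consecutive same-limb heel-strikes with the unique toe-off
between them.

## Detection rules

A sign change of ω is the candidate (− → + ⇒ HS, + → − ⇒ TO).  Exact-zero
samples inherit the previous nonzero sign, so touching zero is not an
event and a zero run yields at most one crossing, timed at the run's
first zero; elsewhere crossing times are sub-sample by linear
interpolation.  Candidates pass through the rules in a fixed order
(rejection is attributed to the first failing rule, which keeps the audit
log stable):

1. **Event timer** — reject within the segment's blocking time of the
   limb's last accepted event (shank 150 ms, leg 200 ms, extended leg
   250 ms; kept as small as safety allows so a stumble heel-strike is not
   masked).  Candidates are rejected, never deferred.
2. **Heel-strike rule** — reject a candidate of the same kind as the
   limb's last accepted event.
3. **Opposite-leg rule** (TO only) — require an opposite-limb heel-strike
   newer than the limb's own last heel-strike and not later than the
   candidate.  Not enabled for the extended leg, whose toe-off crossing
   can precede the opposite heel-strike.
4. **Segment-angle rule** (TO only) — a reference angle is latched each
   time ω rises above −50 °/s (re-latched on every upward crossing);
   toe-off requires the angle to have advanced ≥ 15° in the stance
   direction since the latch.  The displacement is *signed*: unsigned
   change could arm during swing oscillations.  This rule exists to
   suppress toe-offs while standing and is off in the per-segment
   defaults (constant-speed walking does not need it) but fully
   implemented and tested.

The machine starts in standing with heel-strike as the initial
condition.  Taken literally together with rule 3 this deadlocks at
stream start (every HS is "a repeat", every TO lacks an opposite HS), so
the start registers a *virtual* heel-strike of both limbs: it counts as
double support for the opposite limb's first toe-off but not as the
limb's own last real heel-strike.  Steady-state behaviour is unaffected;
only the first event or two at stream start differ.  Simultaneous
left/right candidates at the same sample are processed left first, and
candidates are ordered by the sample at which they become observable, so
truncating the input never changes earlier decisions (causality is
property-tested).  The thigh has no workable rule set — its velocity
profile has too many crossings away from the events — and its config is
constructible but flagged unsupported.

An optional causal 2nd-order 4 Hz low-pass can be applied to ω before
detection (`prefilter_cutoff_hz`); it reduces noise crossings at the cost
of lag and is off by default.

## Evaluation metrics

Reliability = zero crossings per stride, per direction and total (both
are reported; the ideal is one each).  Accuracy = timing offset of a
detected event against its force-based reference event, as a percentage
of the stride containing the *reference* event; negative = early.
Matching is greedy nearest-in-time within ±50 % of that stride, each
event used at most once.  Aggregation is two-stage — strides → subject
mean, subject means → group mean and SD — so subjects with more strides
do not dominate.

## Synthetic gait model

The generator replaces unavailable treadmill recordings and defines the
study conditions; its defaults were fixed at design time.

* **Trajectories.**  All segment angles of a limb follow one shared
  periodic stride-phase shape built from two quintic arcs with matched
  junction curvature, so the velocity is C¹ with exactly two transversal
  zeros per cycle: one at phase `−retraction_lead` before the force
  heel-strike (swing-leg retraction; default 4 % of the gait cycle, the
  middle of the band typical for unimpaired walking) and one at the
  stance/stride duty fraction.  The quintic construction (rather than,
  say, a low-order Fourier table) is what lets both crossing phases be
  pinned exactly without spurious extra crossings, and its C¹ velocity
  keeps the 10 Hz zero-lag marker filter from biasing the crossing times
  (a velocity-slope corner at the crossing shifts the filtered zero
  toward the shallow side by ~0.6 % of the cycle).  Each segment has an
  (offset, range-of-motion) pair — thigh (−5°, 40°), shank (20°, 65°) at
  1.3 m/s — scaled with speed and shifted with slope.  Because the
  virtual segments are monotone compositions of thigh and shank, every
  segment inherits exactly the same two crossing phases.  The
  contralateral limb is the same trajectory shifted half a stride.
  Stride time (≈ 1.05·(1.3/v)^0.42 s) and duty factor (≈ 0.62 −
  0.055·ln(v/1.3), clipped to walking range) follow speed.
* **GRF.**  Per limb, stance is a smooth double-hump
  `sin(πs) + 0.42·sin(3πs)` (normalised, peak 1.1 body weight, zero at
  contact onset and end), stance duration = duty·stride, belts offset
  half a stride.  Body mass defaults to 69.5 kg; below ~37 kg the peak
  would not clear the 400 N trigger and generation refuses.
* **Ground truth.**  Heel-strike truth is the analytic contact onset;
  the reference backward scan recovers it within one sample, which is a
  genuine closed-loop check.  Toe-off truth is the sub-sample 10 N
  downward crossing of the 20 Hz-filtered *clean* force — i.e. the
  force-reference definition applied to the noise-free trace — because
  the filtered crossing is inherently ~1.5 ms before the analytic
  contact end and is the only toe-off a force reference can ever report.
  The constructed kinematic reversal times are stored separately as
  `kinematic_truth`.
* **IMU model.**  Gyro = derivative of the angle resampled to 133 Hz,
  plus white noise, a bias random walk, and a damped 20 Hz sinusoid
  (τ = 50 ms) after each heel-strike — full amplitude for the own limb,
  half for the opposite (the shock travels through the body).
  Accelerometer = gravity components of the angle plus optional
  lever-arm motion terms (tangential + centripetal at `lever_arm_m` from
  the joint) plus white noise.  Presets: `none`, `lab` (3 °/s white,
  0.05 °/s·√s bias walk, 0.03 g accel, 80 °/s impact), `worst` (10 °/s,
  0.15, 0.08 g, 160 °/s, 0.2 m lever arm).  The `lab` preset contains
  exactly the protocol's noise sources and no lever arm: the lever-arm
  term biases the fused angle periodically through the (slow) Kalman
  correction and shifts heel-strike detection a further ~0.6–0.8 % of
  the cycle early — a real phenomenon of accelerometer motion artefact,
  reproducible with the `worst` preset or any nonzero `lever_arm_m`, but
  a confound in a parameter-recovery experiment.
* **Markers.**  Hip fixed over the treadmill (no pelvis translation or
  vertical bobbing), knee and ankle from the segment vectors, 200 Hz.
* **Reproducibility.**  One integer seed per trial; the four IMU noise
  streams use SeedSequence-spawned children, so trials are bit-identical
  across runs.

### What the synthetic evaluation shows — and what it does not

The trials are stylised: thigh and shank share one phase shape, so here
*all* segments (including the thigh) have exactly two crossings per
stride when noise-free, the hip does not translate, belts have no
cross-talk, and GRF is noise-free.  Passing tests therefore certify that
the pipeline is internally consistent — filters, fusion, composition,
rules, reference and scoring do what they claim, and the constructed
retraction lead is recovered to a few tenths of a percent of the gait
cycle under lab noise — not that real thighs are reliable (they are
not), nor that real-data offsets equal the synthetic ones.  No figure
digitisation or fitting to published curves was performed.

## Problem sizes

Defaults chosen for the shipped experiments: reliability sweeps use 50
strides per condition over seven speed/slope presets; detector-vs-oracle
equivalence uses 200 five-stride noisy trials with cycled segment
configurations; retraction-lead recovery uses 3 leads × 20 seeds × 15
strides; the acceptance script uses 25 strides per condition.

## Known limitations

* Irregular sampling, marker gaps (NaN) and 3-D joint angles are out of
  scope; the readers reject non-uniform or incomplete streams.
* The thigh segment is exposed but unsupported by design.
* No pathological-gait presets; asymmetry can only be emulated via
  per-limb parameter overrides on the generator's building blocks.
* The evaluation reports descriptive statistics only; no hypothesis
  tests across segments or conditions.
* Event detection is offline-causal: the implementation is strictly
  causal sample-by-sample, but no real-time I/O layer is provided.
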