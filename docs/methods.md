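# Methods

## Orientation gate

Roll and pitch are recovered from the gravity decomposition of the
accelerometer signal in a North-East-Down convention (z down):
θ = atan2(a_y, a_z), φ = atan2(−a_x, √(a_y² + a_z²)), both in degrees.
Yaw is not estimated: rotations about gravity are unobservable from the
accelerometer and carry no information about face-touching anyway.  Pitch
is confined to [−90°, 90°] by construction (the second argument of its
arctangent is non-negative).  A fully zero acceleration triplet is treated
as sensor dropout and rejected; atan2(0, 0) is taken as 0 so degenerate
but non-zero readings still resolve.

The *unsafe* box — orientations compatible with a natural face-touch — is
an open rectangle with strict inequalities, so boundary poses are safe.
Right-handed defaults (watch on the left wrist): θ ∈ (−90°, 70°),
φ ∈ (30°, 100°); the left-handed box is the mirror image (both angles
negated).  The defaults are deliberately round numbers and are exposed as
configuration because individual anatomy varies.

Because only ratios of acceleration components enter the arctangents, the
gate is invariant to the stream's unit (m/s² or g).

## Magnetometer detector

State: a ring buffer of the last N = 200 field magnitudes, a rolling mean
Φ̄ over the last M = 50 entries, and a sample standard deviation σ_Φ over
the full buffer (N−1 divisor).  The buffer updates only while the pose is
safe; in an unsafe pose the background model is frozen and the alert
predicate |Φ − Φ̄|/σ_Φ > α is evaluated with a strict inequality (a tie
does not alert).  The alert clears the moment either condition fails —
there is no built-in debouncing; evaluation-stage event merging via a
`min_gap_s` parameter (default 0) replaces it.

The asymmetric windows (mean over 50, deviation over 200) resolve an
ambiguity in the procedure's original formulation, which mixes both
lengths: the short window makes the mean track slow environmental drift,
while the long window stabilises the noise-scale estimate.  Both are
configuration keys.

Calibration: phase 1 (≈2 s, arm far from the magnets) fills the buffer and
fixes Φ̄ and σ_Φ; zero variance is a hard error, since a noise scale of
zero makes the z-score meaningless (synthetic noiseless streams are the
usual cause).  Phase 2 (≈3 s, approaching the necklace to ≈20 cm) records
the running maximum Φ̂ and sets α = |Φ̂ − Φ̄|/σ_Φ.  A phase-2 maximum not
exceeding the baseline raises a warning: α ≈ 0 would alert on any
deviation.  For a purely Gaussian environment α = 3 would bound the
per-sample false-alert probability near 0.27% (the 3σ interval, verified
by simulation in the test suite); the calibration instead absorbs the
burstiness of real magnetic environments, and simulated calibrations land
around α ≈ 20.

When a detector is rebuilt from a stored calibration without its original
buffer, the ring is primed flat at Φ̄.  A constant buffer cannot furnish a
noise scale, so if the rolling σ_Φ evaluates to zero the calibrated value
is retained until genuine safe samples refresh it.

Sampling is 100 Hz for both sensors; the accelerometer rate is assumed
equal to the magnetometer's and both are configurable.  Calibration phase
lengths are wall-clock (2 s ≈ 200 samples at the default rate).

## Inertial detector

The pitch rate φ̇ is the raw successive difference in degrees *per sample*
(not divided by Δt), so the threshold β scales with the sampling rate;
calibration and monitoring must share a rate.  β = 3·σ_φ̇, with σ_φ̇ the
sample standard deviation of φ̇ over a ≈2 s still-arm recording (buffer
capped at 200 differences; the first sample has no predecessor and
contributes none).  A noiseless recording yields β = 0 with a warning
rather than an error — the detector then marks any upward pitch change.

Monitoring pushes +1 into a 50-element slope ring when φ̇ > β, else −1;
the ring is pre-filled with −1 so the detector starts non-rising and the
first eviction is well defined.  "Rising" is a strict sign test on the
ring mean (an exact 25/25 split is not rising; the divisor — ring length
vs. buffer capacity — only scales the mean by a positive constant and
cannot change the sign).  Alert ⇔ unsafe pose AND rising.  The first
monitored sample's φ̇ is taken as 0.

## Simulator

The simulator emulates what the watch sees during scripted gestures near a
magnet necklace:

* **Magnets.** Point dipoles.  The default moment (0.2625 A·m²) is
  calibrated so one magnet yields 420 μT on axis at 5 cm, matching bench
  measurements of the 10 mm × 5 mm N42 discs; the moment implied by
  nominal N42 remanence (≈0.41 A·m²) over-predicts a real disc magnet's
  near field and is available via `MagnetSpec.nominal_moment`.  The field
  follows the physical 1/r³ dipole law.  Five magnets sit 4.5 cm apart
  (neighbour chord) on a shallow arc (radius 0.18 m) in the chest plane,
  moments aligned horizontally out of the chest; the necklace pose is not
  pinned down by any measurement, so the arc parameters are configuration.
* **Environment.** A uniform Earth field, default 45 μT (middle of the
  25–60 μT surface range) at 60° inclination; white sensor noise with
  σ = 0.02 m/s² (accelerometer) and σ = 1 μT (magnetometer), typical of
  consumer MEMS parts at 100 Hz; optional Poisson-timed exponentially
  decaying EMF bursts (default off) standing in for appliance
  interference.
* **Gestures.** Keyframed wrist trajectories: minimum-jerk position
  blending, linear angle interpolation.  Reaches model the empirical
  kinematics of arm raises: the wrist pre-orients early (rotation complete
  by 60% of the reach) while the hand's translation lags (stationary for
  the first 45%), so the pose crosses into the unsafe box while the hand
  is still far from the chest — which is precisely what lets the
  background model freeze on clean data.  Face-touches end 6.5–9.5 cm
  from the necklace centre inside the unsafe box and carry a ground-truth
  contact window; the four ADL confounders (spoon, mug, comb, shirt-pull)
  enter the unsafe box while rising but keep the wrist 0.25–0.35 m from
  the necklace, outside the 0.12 m face-touch proximity radius.  All
  timings, end poses and distances are jittered per instance.
* **Rendering.** The accelerometer reads gravity rotated into the sensor
  frame (yaw 0) plus noise — gesture-induced linear acceleration is *not*
  added, matching the gravity-vector assumption the detectors make; the
  magnetometer reads the superposed necklace + Earth field at the wrist,
  rotated into the sensor frame, plus noise.  All randomness flows from a
  single seed and regeneration is bit-identical.

The benchmark renders 30 face-touch and 30 ADL gestures in pseudorandom
order, mirroring a laboratory protocol in which participants perform 30
face-touch attempts and 30 confounder gestures.  What passing benchmarks
show is that the *algorithms* behave as specified under their own
assumptions; they do not certify performance on real arms, where motion
acceleration contaminates the gravity estimate, magnetic clutter is
non-Gaussian, and gesture kinematics are richer than five keyframes.

## Evaluation and statistics

Alert flags segment into maximal events; events closer than `min_gap_s`
merge.  Duration < 1 s classifies an event as a Touch Attempt, otherwise a
Happened Contact with recorded duration = excess over 1 s (exactly 1 s is
an HC: an attempt is defined as lasting *less* than a second).  A
face-touch counts as detected if any alert sample falls inside its contact
window ± 0.5 s (the matching tolerance is a parameter; no standard rule
exists); an ADL with any alert is a false positive.

The condition-comparison battery runs a Shapiro–Wilk gate on the pooled
data with a square-root fallback transform (applied to both samples when
the raw data fail at α = 0.05; negative inputs are an error), a two-sided
paired t-test (zero-variance differences are degenerate), and post-hoc
power of the paired t-test from the noncentral t distribution with
ncp = d_z·√n, df = n − 1, where d_z is the mean difference over the SD of
differences — by default evaluated at the observed d_z = |t|/√n.
Two-sided p-values throughout.  At large noncentrality the opposite-tail
term can underflow in scipy's noncentral-t CDF and is then dropped (it is
below 10⁻⁹ whenever this occurs).

## Problem sizes

The bundled suites use 100-Hz streams of a few seconds: the 60-stream
benchmark, a 100-stream streaming-vs-batch equivalence sweep, 10⁵–10⁶-draw
Monte-Carlo checks for the coverage and false-alert-rate properties.
These sizes give binomial standard errors comfortably inside the asserted
tolerances while keeping the whole pipeline interactive.

## Known limitations

* No gyroscope fusion: fast wrist motion corrupts the gravity-based
  angles; the simulator deliberately does not model this failure mode.
* No hard/soft-iron magnetometer calibration and no magnet pose
  estimation — only magnitude thresholding.
* The necklace geometry and the calibration-approach path are idealised;
  ferromagnetic clutter near the user during calibration is not modelled
  and no mitigation is specified.
* TA/HC classification infers contact from alert duration alone; without
  hand-position ground truth a long non-contact hover in the unsafe zone
  near the magnets is indistinguishable from a contact.
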