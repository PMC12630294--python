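# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `femkit`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and interval conventions

Gaze is expressed in degrees of visual angle from the participant's view:
origin at the calibrated zero point, +x rightward, +y upward.  Directions
use atan2 with +y up, reported in [0°, 360°) with 0° = rightward and
90° = upward.  All time intervals are half-open `[t_on, t_off)` and sample
indices are 0-based; event index pairs (onset, offset) are inclusive.

## Input handling and calibration

The canonical gaze file is delimited text `t_s,x_deg,y_deg,valid`; a
`GazeDialect` remaps column names and units so externally deposited
datasets can be adapted without touching the pipeline.  Samples with
missing positions stay missing — nothing is interpolated anywhere in the
pipeline, on the principle that fabricated positions would contaminate
velocity estimates and event displacements.

Zero-point calibration takes the per-axis **median** of valid samples
pooled over the central-fixation windows, after dropping the first 0.5 s
of each window (the saccade acquiring the target).  The median rather
than the mean makes the zero point insensitive to saccades and transients
within the calibration fixations; applying the offset and re-calibrating
yields (0, 0) exactly.

## Data quality

RMS-S2S is √(mean(Δx² + Δy²)) over consecutive valid sample pairs,
converted to arcmin; pairs spanning an invalid sample are skipped.  For
white per-axis noise of SD σ this equals 2σ, the identity the noise
generator is calibrated against.  Data loss is simply the invalid-sample
fraction.

## Microsaccade detection

The detector is the Engbert–Kliegl velocity-threshold method with the
published toolbox defaults: velocity window 5 samples, minimum event
duration 3 samples, per-axis median-based σ with the elliptic threshold
combination.  The velocity stencil generalises to any odd window
`w = 2m+1` as

    v_n = Σ_{k=1..m} (p_{n+k} − p_{n−k}) / (2 Δt Σ_{k=1..m} k),

which reduces to `(p_{n+2}+p_{n+1}−p_{n−1}−p_{n−2})/(6Δt)` at w = 5 and
the plain central difference at w = 3.  Δt is the segment's median sample
interval — the stencil assumes uniform sampling, and the median is robust
to timestamp jitter.  Velocities whose stencil touches an invalid or
out-of-range sample are undefined, and threshold estimation uses defined
samples only.  A σ below 10⁻⁹ deg/s raises a degenerate-signal error
rather than producing an everything-is-a-saccade threshold.

Post-detection processing, in order, with defaults matching the study's
analysis settings:

1. **Merging** (gap < 20 ms, measured end-of-event to start-of-next,
   iterated to a fixed point) absorbs post-saccadic oscillations.
2. **Finalisation**: displacement from the last sample before onset to
   the first sample after offset; candidates without valid flanking
   samples, or containing a data-loss run, are dropped and logged.
3. **Minimum displacement** (4′) filters after merging, because merging
   changes event extents.  The filter applies to the operationalised
   pre-onset→post-offset displacement, not the raw supra-threshold
   excursion.
4. **Drift coding**: complement intervals — including the stretches
   before the first and after the last saccade, since a literal
   "between saccades" reading would discard most drift in low-rate
   segments — kept when loss-free and longer than 100 ms.
5. **Exclusions**: saccades with onset in the first 0.5 s of a segment
   (target-acquisition after a mask interval) or starting/landing beyond
   2.5° from the target center; drift episodes starting in the warm-up or
   with mean position beyond 2.5°.  A discard log counts removals per
   rule.

Detection is deterministic: identical input and parameters give identical
events.  The test suite checks the composed chain event-for-event against
an independent brute-force per-sample scan.

## Fixation metrics

BCEA is parametric (Crossland & Rubin convention): sample SDs and Pearson
correlation of the pooled positions inside selected events, with
`area = 2π k σx σy √(1−ρ²)`, `k = −ln(1−P)`, default P = 0.6827
(±1 SD coverage).  A quantile-based empirical ellipse was deliberately
not used; the parametric form matches the BCEA literature and converges
to the stated coverage for normal data, which the tests verify at
n = 10⁵.  Fewer than 3 points, zero variance, or collinearity raise a
degenerate-geometry error.

Drift speed uses `numpy.gradient` (second-order central differences
interior, first-order one-sided at the two episode boundary samples) and
averages the 2D velocity magnitude.  Saccade rate divides the selected
saccade count by the analysed duration — segment duration minus the 0.5-s
warm-up (29.5 s for a 30-s trial).  Time lost to data loss is *not*
subtracted: at sub-percent loss levels the bias is negligible and the
denominator stays comparable across segments.

Aggregation averages per-event metrics within a segment, segments within
participant × target × polarity across sessions, then across participants
with equal weight, so a participant with six sessions counts the same as
one with three.  Missing participant × condition cells are reported,
never silently dropped.

## Density maps

Displacement vectors (Δx, Δy) are smoothed with a Gaussian product kernel
using per-axis Silverman bandwidths `h = σ n^(−1/6)` on a regular grid
(default 128², data range padded by 3 bandwidths), normalised per panel.
The rule-of-thumb bandwidth stands in for adaptive diffusion-based
selectors: the visualisation, not the bandwidth selector, is the point,
and the Silverman choice is reproducible in closed form.  Contour
discretisation uses 22 equally spaced levels in (0, max], with the lowest
level omitted when rendering.

## Synthetic gaze generator

Defaults emulate the empirical regime of a high-precision retinal-tracker
fixation study: 30-s trials at 620 Hz, drift speed 0.76 deg/s, saccade
rate 1.8 Hz before refractory thinning (~1.55 Hz effective at a 150-ms
dead time), lognormal amplitudes with 0.25° median and 0.35 log-SD, two
opposed von Mises direction modes (κ = 8), 30% square-wave-jerk pairing
with a 0.2-s return latency, sensor noise 0.156′ RMS-S2S, and loss
episodes of 0.1 s at 0.065 Hz (~0.65% expected loss).

Mechanics and the reasoning behind them:

- **Directed drift** takes constant-length steps `drift_speed/rate` with
  a heading performing a von Mises random walk (κ default 50), so the
  realised mean step speed equals the target exactly.  An optional
  `drift_bias_pull` weakly reverts the heading toward a bias direction to
  emulate a persistent per-participant drift direction; its default is 0
  because a concentrated heading makes the along-drift velocity nearly
  constant, which deflates the detector's median-based σ — an artefact of
  the constant-step idealisation, not a property of real drift.
  **Diffusion drift** uses isotropic Gaussian steps matched in expected
  speed and has no such pathology.
- **Saccade timing** is a Poisson process thinned by a refractory dead
  time (realised rate ≈ rate/(1 + rate·refractory)).
- **Waveforms** are raised-cosine position profiles with duration
  `max(6 ms, 21 ms + 2.2 ms/deg × amplitude)` (a linear main-sequence
  rule); the analysis measures displacement, not waveform shape, so any
  smooth monotone profile with exact net displacement suffices.
- **Recentering**: each non-SWJ saccade's displacement is its sampled
  vector minus `recentering_gain ×` the current offset from the trial
  center.  This is the simplest closed-loop rule that keeps 30-s traces
  near the target (gain near 1 keeps them within the 2.5° exclusion
  radius, so exclusion rules fire on essentially no events); the ground
  truth records the *executed* net vector, so recovery comparisons remain
  exact regardless of the gain.
- **SWJ returns** exactly undo their primary after the return latency; a
  return pre-empted by another saccade is skipped (a new saccade command
  supersedes the pending correction), and ground truth labels each SWJ
  member's role.
- **Noise** is i.i.d. Gaussian with per-axis SD `target/2`, making the
  measured RMS-S2S of a static trace equal the target.
- **Data loss** marks Poisson-scheduled intervals invalid with positions
  removed (NaN), as a tracker that lost the retina would.

Everything draws from one `numpy` generator, so identical config + seed
give byte-identical recordings, ground truth and manifests.

## Validation problem sizes

The test suite and acceptance script validate at desk scale: BCEA
coverage/area on 10⁵ points, detector–oracle agreement on 100 random
2,000-sample segments spanning both drift modes and loss/no-loss,
recovery on 20 simulated 30-s sessions (amplitudes truncated at 6′, noise
0.16′), and drift-speed recovery on noise-free sessions.  The noise-free
condition for drift speed is deliberate: mean |v| is biased upward by the
sensor-noise floor (at 0.156′ noise the per-axis velocity noise is
~0.28 deg/s, inflating a 0.76 deg/s drift estimate by ~25–30%), so a
speed-recovery check against the configured value is only meaningful
without noise.  The same bias applies to real recordings; drift-speed
comparisons are therefore meaningful across conditions measured at the
same precision, not as absolute speeds.

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis assumes —
event rates, amplitude/direction distributions, noise level, loss — but
not physiological detail: no self-avoiding-walk or control-theoretic
drift models, no tremor, no main-sequence velocity-profile variability,
no pupil-size or head-movement artefacts (the motivation for retinal
tracking is precisely their absence), and no binocular structure.
Passing recovery tests therefore demonstrate the pipeline's correctness
under its own model assumptions, not detector performance on
arbitrarily pathological real data.

## Known limitations

- The detector estimates thresholds per segment; no adaptive λ.
- Peak saccade speed is read from the smoothed velocity series and
  inherits its low-pass bias.
- `aggregate` assumes one segment per target per session; duplicated
  labels within a session are averaged together.
- The deposited-data adapter covers delimited text via `GazeDialect`;
  proprietary binary formats are out of scope.
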