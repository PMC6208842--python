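# Methods

This note documents the models, detectors and numerical choices behind the
`gonogo` package: a pipeline for a trajectory-prediction go/no-go task in
which an observer fixates a cross at +20° of visual angle, watches a dot fly
in a straight line toward one of eight final locations around a 10°×10°
target square, and must touch the screen before the dot lands if — and only
if — it will land inside the square.

## Task design

The task geometry lives in degrees of visual angle, origin at screen
center, y up, for a 75°×46° screen viewed at 460 mm. The eight final
locations form a 4×2 grid around the target square: columns at
x = ±side/4 (inside the square → go) and x = ±3·side/4 (outside, two per
lateral side → no-go), rows splitting the square's vertical span
symmetrically, so neighboring grid points are equidistant (side/2 = 5°)
both horizontally and vertically. The published constraints fix only the
angular layout, not the absolute placement on the physical screen; the
square is centered at (0, −15°) so the full flight subtends ≈ 37.6°.

One block holds 80 trials: 3 flight durations (385/485/585 ms) × 8
locations × 3 repetitions, plus 8 probe trials (985 ms, one per location,
fixation fixed at 1000 ms). Fixation durations (390/890/1900 ms) are
assigned so that each appears 24 times per block, three times per location,
and eight times per flight-speed cell. Rather than searching for such an
assignment, the generator uses a cyclic (Latin-square-style) rule over the
(location, speed, repetition) cells, with fixation labels, speed labels and
the cyclic phase permuted from the seed, then shuffles trial order with the
same stream. The construction makes every count exact by algebra — for any
residue class, 8 locations × 3 repetitions contribute exactly 8 cells — so
no backtracking or rejection sampling is needed, and identical
(design, seed) inputs always yield identical schedules. Infeasible count
combinations (e.g. a number of fixation levels that does not divide the
per-location trial count) raise with the violated constraint named.

Every stimulus duration carries a per-trial jitter drawn from {−5, 0, +5} ms,
mimicking the asynchrony between a 60 Hz display and the 200 Hz recording
clock; the jitter is stored in the trial spec so downstream analysis is
exact rather than approximate.

## Synthetic subjects

The simulator exists so every extraction stage can be validated by
parameter recovery against known ground truth. It emulates the trace
statistics that matter to the detectors, not oculomotor physiology (no
main-sequence model, no neurally grounded pupil model).

* **Decision.** Equal-variance signal detection: evidence
  e ~ N(d′(speed)·1{go}, 1); the subject touches iff e exceeds a fixed
  threshold λ on the evidence axis (the reported bias c = −(z(H)+z(F))/2
  is computed downstream, not a generator parameter). Default
  sensitivities are d′ = 1.14/1.99/2.25 (control) and 1.48/2.19/2.57
  (expert) for fast/medium/slow, with λ = 0.8. Touches land at hand
  reaction + movement duration after stimulus onset, so a slow draw on a
  fast trial produces a *late* touch — classified as a miss — giving the
  task its second miss mechanism besides "decided no-go".
* **Gaze.** Fixation gaze = cross + slow drift (direction random per
  trial, rate per profile; experts drift less, which is what makes their
  fixation error smaller on long fixations) + white noise (0.3° SD).
  After a Gaussian saccadic latency (210 ± 25 ms) the gaze saccades to the
  stimulus position expected at landing, then pursues the stimulus with a
  lag (≈100 ms) and gain (≈0.5). Pursuit gain stays below ~0.5 by default
  because the fast stimulus itself moves at ≈98°/s: higher gains would hold
  gaze speed above the 50°/s saccade threshold for the whole flight and
  make saccade-offset detection meaningless.
* **Speed profiles.** Saccade and hand speed bursts are trapezoidal with a
  10 ms rise. A smooth bell profile would cross the detection threshold
  tens of ms after true onset; the trapezoid crosses within one sample, so
  detector equivalence with ground truth can be held to ±5 ms.
  Saccade peak velocity scales with amplitude (30 °/s per degree, clipped
  to [80, 600] °/s).
* **Pupil.** Diameter = baseline (3.6 mm) + a linear ramp across the
  fixation period (the fixation slope parameter, mm/s) + a task-evoked
  dilation: an Erlang-style kernel (z^s·e^{s(1−z)}, shape s = 4) anchored
  at stimulus onset and peaking at the profile's per-condition
  latency-to-peak, + white noise (0.015 mm SD). Anchoring the kernel at
  stimulus onset keeps the fixation period purely linear, so the fixation
  slope is identifiable; the peak time parameter itself is expressed from
  trial onset. Expert latency tables peak ~75 ms earlier than controls at
  the short fixation and ~250 ms later at the long fixation; flight-slope
  differences (shallower expert slope at the fast speed) then emerge from
  the kernel timing rather than being set directly.
* **Blinks.** Poisson onsets (12/min) with a fixed 150 ms duration; the
  affected samples are flagged and blanked. Hand-speed noise is clipped
  strictly below the 20°/s threshold so no-touch trials never trigger the
  hand detector.

Everything is driven by per-trial child streams spawned from a single
session seed, so sessions are reproducible to the byte.

What the generator does **not** emulate: pink/drift noise and tracker
calibration error in gaze, pupil foreshortening, touch-and-release
dynamics, learning across blocks, or the empirical effect magnitudes of
real expert/control cohorts — the preset differences are directions, not
sizes. Passing recovery tests therefore demonstrates that the detectors
measure what they claim on well-behaved traces, not that real recordings
would be this clean.

## Trial QC and outcome extraction

The QC gate replaces a manual blind rating with explicit rules, applied
per trial: (1) a missing-sample run overlapping a critical window — first
100 ms of the trial, stimulus onset ±50 ms, or the last 100 ms of the
stimulus presentation — or longer than the 200 ms interpolation cap
invalidates the trial ("blink"); (2) more than 30% missing samples
invalidates it ("missing"); (3) gaze off the screen in more than 20% of
samples invalidates it ("offscreen"). Shorter gaps are linearly
interpolated in gaze and pupil. Non-monotone timestamps are an input
error, not a QC outcome.

Angular gaze velocity is the central difference of position smoothed with
a 5-sample (25 ms) moving average — a compromise between the 200 Hz noise
floor and onset bias. Detectors use strict first-crossing semantics:

* eye response time = first post-onset sample with speed > 50°/s; the
  saccade ends when speed stays ≤ 50°/s for 2 consecutive samples, and the
  primary saccade amplitude is the gaze displacement between those samples;
* hand response time = first post-onset sample with finger speed > 20°/s
  (the hand channel is taken as recorded, not differentiated or smoothed);
* tracking = flight samples (half-open [onset, flight end)) with
  gaze-stimulus distance < 8°; total tracking time is 5 ms per sample, the
  percentage uses the jittered flight duration as denominator (tracking is
  undefined before stimulus onset), and mean gaze-stimulus distance is
  averaged over tracking samples only, hence always < 8°;
* fixation error = mean Euclidean distance from the cross over the whole
  fixation period.

The moving-average smoothing leaks saccade velocity ~10 ms backward, so
the detected onset runs 0–10 ms *early* for fast saccades; the recovery
suite bounds this at two sample periods. A touch recorded before the hand
velocity crossing is flagged "inconsistent kinematics" rather than
silently accepted. An outcome parameter enters subject-level analysis only
with ≥ 10 reliable trials.

Pupil outcomes use 100 ms window means (≥ 10 finite samples or the field
is absent), OLS slopes over whole trial / fixation / flight, and the
global maximum over [trial onset, stimulus end] for peak size change and
latency-to-peak (earliest sample wins ties; feedback is excluded because
the trial clock for pupil dynamics starts at fixation onset). Both
trial-onset- and stimulus-onset-referenced latencies are emitted.

## Performance and statistics

Responses classify as hit (go, touch before flight end), miss (go, no or
late touch), correct rejection (no-go, no touch) and false alarm (no-go,
any touch); the "hold" component of a real touch-and-hold response is
collapsed into the touch event. d′ = z(H) − z(F) with a log-linear
correction by default (add 0.5 to every cell; a 1/(2N) clamp is
selectable) because extreme rates at 72 trials per cell are common.
Percent-correct tables are produced per block, speed, fixation duration
and speed×fixation cell; probe trials are excluded from these tables by
default (configurable) since they are calibration trials with their own
fixation duration.

Reaction-time-task presses are filtered before summarizing: < 125 ms is a
catch trial, > 750 ms or missing is invalid, negative press times are
premature; boundaries are inclusive of the valid side.

Group comparisons are normality-gated: Shapiro-Wilk at α = .05 per group
routes to an independent-samples t test / ANOVA (mixed ANOVA with
Bonferroni-corrected post-hocs when a within factor is supplied, via
pingouin) or to the Mann-Whitney U test. Groups below the Shapiro minimum
(n = 3) or with zero spread route to the nonparametric branch. One-tailed
alternatives are available by flag for directional hypotheses.

## Problem sizes and tolerances

The shipped validation suite runs at desk scale: detector oracle
equivalence on one noise-free 80-trial block (±5 ms, one sample period);
d′ recovery at 72 go + 72 no-go trials × 50 replicates (|bias| < 0.15 —
the log-linear correction plus the ~3% late-touch rate on fast trials
biases d′ down by ≲ 0.08); pupil latency/slope recovery at 24 trials per
condition × 50 replicates (10 ms / 5%); cross-subject recovery for 20
simulated subjects at 240 trials each; partition and tracking-conservation
invariants over 100 single-block sessions; and a deterministic end-to-end
run with 2 subjects per group × 3 blocks. These sizes are the package's
validation design; larger runs only tighten the same estimates.

## Known limitations

* The eight-location grid's absolute placement on the physical screen is a
  package choice; only the angular constraints are published.
* Saccade-onset detection inherits a small early bias from pre-smoothing
  (see above); choose `smooth_samples=1` to trade bias for noise.
* The simulator's effect magnitudes are plausible defaults, not estimates;
  group-level statistics on simulated cohorts validate the machinery, not
  human effect sizes.
* Real recordings are supported only through the documented CSV dialect;
  vendor-native tracker formats are out of scope.
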