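# Methods

This note records the models implemented in saccadekit, the parameter choices
that matter, what the synthetic-data generator does and does not emulate, and
the numerical decisions taken where the procedure was genuinely open.

## Signal model and preprocessing

Input is a uniformly sampled gaze trace (nominally 1 kHz): time in ms,
horizontal and vertical eye position in degrees of visual angle, and a
per-sample validity flag from the tracker. Internally x is positive rightward
and y positive **upward**; screen-style y-down sources are flipped at read
time (`y_down=True`), so that a "90°" saccade direction literally means
upward. All internal speeds are in °/ms (30°/s = 0.03°/ms).

Preprocessing is order-fixed: blink excision → interpolation → smoothing →
differentiation.

- **Blink excision.** Video trackers corrupt the samples flanking a blink as
  the lid progressively occludes the pupil, producing spurious high-velocity
  excursions. From each edge of every tracker-reported gap we march outward
  through valid samples while the one-step speed (taken on the away-from-gap
  step, since the gap side holds undefined positions) exceeds 30°/s,
  invalidating as we go. The march is capped at 50 ms per side; without a cap
  a pathologically noisy trace could unravel indefinitely, and 50 ms
  comfortably covers observed lid artifacts.
- **Interpolation.** Invalid spans are replaced with natural cubic-spline
  values fit on the valid samples. Edge gaps have no bracketing data and are
  filled by holding the nearest valid value; a spline extrapolation there
  would manufacture velocity out of nothing.
- **Smoothing.** 3rd-order Savitzky–Golay, window 15 samples, applied to x
  and y independently. Edges are handled by refitting the polynomial on the
  truncated window (no zero padding), so polynomials up to cubic pass through
  untouched everywhere. On noiseless synthetic sessions the smoothing changes
  the peak saccade speed by under 2% for the typical event; the attenuation
  grows toward ~5% for the very shortest (≈16 ms) saccades, which is the
  price of a 15 ms window and is shared by any pipeline using it.
- **Speed.** Central differences of the smoothed positions (one-sided at the
  trace ends), then the Euclidean norm. A config flag
  (`savgol_derivative=True`) instead takes the filter's analytic first
  derivative; the two-step smooth-then-differentiate form is the default
  because it matches the pipeline description the detection thresholds were
  tuned under.

## Saccade detection

A candidate is a maximal run of samples with speed strictly above 0.03°/ms
lasting at least 10 ms; onset is the first sample of the run and offset the
last sample before speed drops below threshold. A single sub-threshold sample
separates events (no additional inter-saccade gap is imposed). Screening
rules and their rejection labels, applied in order with the first failure
reported:

| rule | bound | label |
|---|---|---|
| trace-boundary contact | onset/offset at the first/last sample | `boundary` |
| magnitude | > 1° and < 40° | `magnitude_low` / `magnitude_high` |
| duration | > 15 ms | `duration_short` |
| onset-sample speed | < 0.075°/ms | `initial_velocity` |
| offset-sample speed | < 0.3°/ms | `terminal_velocity` |
| speed at onset + ⌊duration/4⌋ samples | ≥ 0.15 × peak | `slow_first_quartile` |

The first-quartile speed is read at a single sample (not averaged); the
instant reading is deterministic and the averaged variant was not observably
different on synthetic cohorts. Boundary events are rejected because both
their kinematics and their profile fits are truncated.

Orientation: horizontal within ±5° of 0°/180°, vertical within ±22° of
90°/270° (band edges inclusive), otherwise oblique; `leftward` means
direction strictly inside (90°, 270°), `downward` strictly inside
(180°, 360°) under the y-up convention.

## Curvature

Pointwise curvature of a sampled path, for interior samples t:

    k_t = ‖p_{t+1} − 2 p_t + p_{t−1}‖ / Σ_t ‖p_t − p_{t−1}‖

and the saccade's curvature k is the **median** of the k_t series. Both
numerator and denominator are lengths, so k is dimensionless and invariant
under rotation, translation and uniform scaling (verified to 1e-10).

Two variants are provided:

- `as_written` (default): the numerator is the full norm of the discrete
  second difference. This includes tangential (along-track) acceleration, so
  a *straight* path traversed at varying speed — which is what a saccade is —
  scores k > 0. Its value is a blend of geometric bending and speed-profile
  shape.
- `perpendicular`: the numerator keeps only the component of the second
  difference orthogonal to the local tangent (p_{t+1} − p_{t−1}). This is
  zero on any straight path and isolates geometric curvature.

Consequence worth knowing: over synthetic saccades with a growing injected
bow (0 → 0.9° at 5° magnitude), the perpendicular k is strictly increasing
(Spearman ρ = 1), while the as_written k is only weakly monotone — for small
bows the tangential term dominates its numerator and the path-length
denominator grows with the bow. Monotonicity guarantees in the test suite are
therefore stated for the perpendicular variant; the as_written variant
remains the default metric for comparability and both are reported by
`attach_metrics` consumers that need them.

Degenerate inputs: fewer than 4 samples or a zero-length path raise.
Alternative curvature measures from the literature (quadratic-polynomial
area; maximum chord deviation) are deliberately not implemented.

## Velocity-profile deviation

The along-track displacement of an event — Euclidean distance of each sample
from the onset-sample position, with time measured from onset — is fit with
the compressed exponential

    f(t) = p1 [1 − exp(−(t/p2)^p3)]

by bounded trust-region least squares (`scipy.optimize.least_squares`):
initialization p1 = event magnitude, p2 = duration/2, p3 = 2; bounds
p1 ∈ (0, 3·magnitude], p2 ∈ (0, 3·duration], p3 ∈ [0.5, 10]; tolerances
1e-10, iteration budget 200 (if exhausted, `converged=False` and the
deviation is still reported). Distance-from-start is used rather than
cumulative path length because p1 is the saccade's *amplitude*; the
cumulative option exists behind `displacement_mode="cumulative"`. The fit
depends only on displacement magnitudes, so it is independent of start
position and direction.

The deviation score is the RMS difference, in °/ms, between the measured
speed over the event and the fitted model's velocity profile. Two residual
conventions are available:

- `discrete` (default): the model velocity is obtained by applying the same
  central-difference operator used for the measured speed to the fitted
  displacement curve, extended one sample beyond each event edge with
  displacement ≡ 0 before onset and the model curve past the offset. With
  this convention a noiseless model-generated saccade scores ≈ 0: the score
  measures genuine departure from the model family, not the O(dt²)
  discretization bias of differentiating a 1 kHz signal (≈1e-3 °/ms for
  typical saccades, which would otherwise floor every score).
- `analytic`: compare against the closed-form f′(t) directly. Simpler to
  state, but carries that discretization floor.

For real (noisy) data the two agree closely; only the noiseless limit
separates them. Note also that detected events begin at the 30°/s crossing,
not at the true (zero-velocity) onset, so even noiseless pipeline output
keeps a small deviation floor (~1e-2 °/ms at 6°) from that truncation; this
is a property of threshold-based detection itself.

With p3 = 1 the model reduces to the standard exponential saturation; the
fit recovers p3 = 1 to better than 1e-3 on such data, and recovers
(p1, p2, p3) of noiseless model trajectories to well under 1%.

## Scene cuts

Frames are grayscale (BT.601 weights 0.299/0.587/0.114, rounded half-up, for
color sources). For each consecutive pair the metric is
log(1e-6 + mean absolute pixel difference); the per-pixel normalization makes
the metric independent of frame size, and the epsilon guards log(0) on
identical frames. Cut candidates exceed the clip's mean + 1 SD of the metric
(computed over all transitions, cuts included — no robust re-estimation);
candidates closer than 5 frames keep the larger metric; and when fade
rejection is on, a run of ≥ 3 consecutive supra-threshold transitions whose
metrics agree pairwise within 10% is discarded as a gradual-fade signature —
an operationalized stand-in for manual fade removal, documented as a
heuristic. The cut is timestamped at the later frame of the pair
(frame_index / frame_rate). A zero-variance metric series yields no cuts. A
saccade is flagged *in-flight* when some cut time lies in its closed
[onset, offset] interval.

## Analysis table and univariable fits

One row per accepted saccade: log₁₀ of curvature, deviation and duration with
their squares and cubes (stored as exact products of the base column and
re-verified on every export), one-hot orientation, leftward/downward flags,
the in-flight flag, time-on-task bin = 1 + ⌊session offset / 30 s⌋, content
ratings recoded low (≤ 1) / medium (2–3) / high (≥ 4), lighting, environment,
genre, and subject age/gender/education. Rows with nonpositive curvature or
deviation (possible for perfectly straight synthetic saccades under the
perpendicular variant) cannot be log-transformed and are dropped with a
logged count. Suggested reference categories for downstream dummy coding:
orientation = horizontal, direction = rightward/upward, genre = comedy.

Crossed-random mixed-effects fitting is intentionally **not** reimplemented:
the package's contribution ends at a correctly coded model table (subject and
clip as crossed random factors, with random slopes for log duration and the
log outcome predictors) plus univariable OLS cubic fits
y ~ 1 + x + x² + x³, solved by least squares with standard errors from
(XᵀX)⁻¹σ̂². A rank-deficient design (fewer than 4 distinct x values) raises.

## Synthetic data

Sessions are scripted: fixations hold position, saccades follow the
compressed exponential along-track with a perpendicular bow
`bow · 4s(1−s)` (s = normalized progress), blinks are validity gaps whose
five flanking samples on each side carry 40–100°/s position ramps (so the
blink-edge cleanup rule is genuinely exercised), pursuit is constant-velocity
drift, and measurement noise is additive white Gaussian on every sample. A
saccade's finite duration is where f reaches 99.9% of p1 — the model is
asymptotic, and this truncation misplaces the endpoint by < 0.1% of the
amplitude. Everything is driven by one `numpy` generator seed and is
bit-identical across runs.

Default study-like conditions (`standard_session_spec`): 1 kHz sampling;
log-normal magnitudes with median ≈ 4° clipped to 1.5–20°; durations from a
linear main-sequence rule ≈ 21 ms + 2.2 ms/°, kept within 16–99 ms; shape
p3 uniform on [1.5, 2.5]; uniform directions; half the saccades bowed up to
0.5°; 150–400 ms fixations; measurement noise sd 0.02°, fixation jitter
0.005°; two ~300 ms blinks and one 8°/s pursuit segment placed in fixation
gaps. The magnitude median and duration range follow the distributions
reported for video viewing; noise and blink scales are typical of 1 kHz
video-oculography.

The bow is a *measurement* stand-in, not an oculomotor model: real curved
saccades are not symmetric single-humped arcs, and no claim is made that the
generator reproduces the physiology of curvature (or binocular disparity,
head movement, or glissades — beyond what the terminal-velocity filter
rejects). Passing tests therefore certify the measurement pipeline — that
known injected curvature, profile shape, cuts and event times are recovered —
not that real data will match any particular distribution.

Clips are stacks of uniform-intensity frames plus i.i.d. Gaussian pixel
noise; cuts are abrupt level steps of ≥ 40 gray levels, fades are linear
ramps. Uniform frames are the minimal structure for which the cut metric's
behavior can be predicted in closed form; textured content would shift the
metric's baseline but not the thresholding logic.

## Problem sizes and determinism

The test suite runs synthetic cohorts at desk scale: 100-saccade sessions for
detection statistics, 50 clips for cut sensitivity, 100 trajectories for
parameter recovery, and one ~5-minute (300k-sample) session to demonstrate
end-to-end throughput; the full suite completes in a few seconds on one CPU.
Every random draw flows from explicit seeds; the full pipeline writes
byte-identical outputs across repeated runs, and `saccadekit all` records
the seed and a config digest in its run manifest.

## Known limitations

- The as_written curvature conflates bending with speed-profile shape (by
  construction); use the perpendicular variant when geometric curvature alone
  is wanted.
- Threshold-based detection truncates event tails below 30°/s, biasing
  detected durations short of true (zero-velocity-to-zero-velocity)
  durations; all downstream statistics are conditional on this operational
  definition.
- Edge gaps in traces are value-held, not extrapolated; events overlapping
  them are typically rejected at the boundary rule.
- The fade-rejection rule is a heuristic signature, tuned to linear ramps; a
  fade faster than 3 frames is indistinguishable from a cut (arguably
  correctly so).
- EyeLink support covers the plain sample-line subset of ASC exports only;
  binary EDF, event lines and pupil data are out of scope, as are video
  containers (frames must be pre-extracted to images).
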