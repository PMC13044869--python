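# Methods

`oddphot` implements the analysis chain of an auditory-deviance fiber-
photometry experiment — stimulus paradigm generation, two-channel
preprocessing, response-component extraction, behavioral preference
metrics, and paired statistics — together with a synthetic-data generator
that produces recordings with known ground truth, so every stage can be
validated by parameter recovery and calibration rather than by eye.

## Stimulus paradigms

Eight paradigms are generated as event tables on a 0.1-ms time grid
(64-bit seconds snapped to an integer sample grid, so long sequences do not
accumulate floating-point drift):

* **Single / brief / multiple-duration presentations** — broadband white
  noise at 80 dB SPL. "Inter-stimulus interval" is read as the
  offset-to-next-onset gap (a 6-s stimulus with a 3-s ISI has a 9-s onset
  period); onset-to-onset spacing is used only where the design is stated
  as an SOA.
* **Dynamic- and constant-change** — 6-s noise with a mid-stimulus level
  decrement at 3 s. Dynamic mode fixes the initial level (80 dB SPL) and
  varies the second stage (80/60/40/20); constant mode applies a fixed
  −40-dB step from varying initial levels. Conditions are interleaved in
  randomized order per seed. Intensity increments are rejected: the designs
  only use decrements, and the drop-positive model below is defined for
  decrements.
* **Repetitive trains** — 100-ms bursts at SOAs of 800/600/400/200 ms,
  1000 presentations per condition, with a 2-s pause *added* after every
  10 stimuli (the 11th onset follows the 10th by SOA + 2 s; a
  pause-replaces-SOA convention is selectable).
* **Oddball** — 500-Hz-wide band-limited noises (2250–2750 Hz vs
  3250–3750 Hz), 150 ms at 800-ms SOA. Deviants occur at exactly 10% by
  block-wise construction: each block of 3000 stimuli holds exactly 300
  deviants, each preceded by at least 4 standards. Placement distributes
  the surplus standards multinomially over the inter-deviant gaps, so role
  counts are deterministic and testable while order remains pseudo-random.
  The sequence opens with at least one full standard run, and after each
  block the two bands exchange roles. Feasibility requires
  p ≤ 1/(min_run + 1); infeasible designs raise. No maximum standard run is
  imposed.
* **Many-standards control** — ten 500-Hz-wide bands whose centers run
  1000–5500 Hz in 500-Hz steps (the grid containing both oddball bands), at
  exactly 10% each via a balanced shuffle. The band physically identical to
  the oddball deviant is labelled `deviant_equivalent`. No minimum spacing
  between deviant-equivalents is imposed.

The analysis standard for each deviant is the stimulus three trials earlier
(configurable n-back); deviants whose n-back slot is out of range or not a
standard are skipped and logged.

## Synthetic recordings

**Response model.** Each stimulus evokes a four-component fluorescence
response in z-units: an onset-positive peak (96 ms, +0.224), an
onset-negative trough (602 ms, −0.860), a sustained intra-stimulus dip
(−0.327), and an offset-positive peak (549 ms after offset, +0.744).
Transient components are asymmetric Gaussian bumps (independent rise/fall
widths: 30/50 ms for the onset peak, 150/200 ms for the trough,
150/250 ms for the offset peak — chosen to reproduce the published
grand-average waveform's sharp alerting peak and slower value/relief
transients); the dip is a boxcar over the stimulus convolved with the
sensor impulse response (unit steady-state gain). Mid-stimulus intensity
decrements add a drop-positive bump with amplitude proportional to the
decrement magnitude (0.0186 z/dB, i.e. 0.744 z at the −40-dB reference) —
the generator encodes change magnitude, not absolute level. Stimuli
shorter than 0.3 s carry neither a separate dip nor an offset peak; brief
bursts produce a single merged trough followed by recovery, matching the
observed brief-burst profile.

**Calibration.** Because the components overlap (and the dip is smoothed
by sensor kinetics), the nominal amplitudes/latencies are not what a
window-based extractor would measure from the superposition. The generator
therefore calibrates itself: at 1 kHz it solves the component amplitudes as
an exact linear system evaluated at the current extremum samples of the
analysis windows, and nudges bump centers (clamped to ±60 ms of nominal)
until the *measured* features equal the targets to <0.5 ms and <1e-3 z.
All durations calibrate exactly except 0.5 s, where the 602-ms trough
target lies past the stimulus offset and physically overlaps the offset
transient; there the trough settles ~54 ms early while all amplitudes stay
exact. Calibration is cached per (kernel, sensor, duration).

**Deviant gain.** For deviant-role events the value-encoding components
(onset-negative trough and intra-stimulus dip) are multiplied by
`deviant_gain`; the alerting onset-positive and the relief offset-positive
are unchanged. The many-standards deviant-equivalent is rendered with gain
1 by default, encoding "no rule-violation enhancement" as the generative
null (configurable through `ms_gain` to test alternatives).

**Sensor kinetics.** The sensor impulse response is a causal difference of
exponentials. The decay constant defaults to 700 ms (a typical
dopamine-sensor off-kinetics scale; exposed in config); the rise constant
(47.4074 ms) is solved so the 10–90% rise time is exactly 70 ms, the
sensor's reported rise.

**Measurement model.** With t in seconds,

    excitation(t) = F0_exc · B_exc(t) · (1 + s(t) + g(t)) + ε_exc(t)
    isosbestic(t) = F0_iso · B_iso(t) · (1 + g(t)) + ε_iso(t)

where `s` is the summed response in dF/F units (1% dF/F per z-unit by
default — sub-z responses of a few tenths of a percent, typical of a
dopamine sensor under moderate stimuli), `B` are double-exponential bleach
profiles with slightly mismatched per-channel constants (5%/τ=60 s +
3%/τ=600 s excitation; 6%/70 s + 3%/700 s isosbestic), `g` is a
multiplicative common-mode artifact (1% sd, <1-Hz low-pass — fiber bending
and motion scale with brightness, which is what lets isosbestic regression
remove them), and `ε` is white measurement noise (4e-4 a.u. per channel on
~1 a.u. brightness, a moderately low-noise lock-in rig; the effective dF/F
noise floor is ≈0.06 z per sample at 100 Hz). Sampling defaults to 100 Hz.
Every rendering returns a ground-truth record of per-event component
latencies (ms) and amplitudes (dF/F units, gains applied).

What the generator does *not* emulate: hemodynamic/pH confounds,
wavelength-specific crosstalk, movement-locked signals, habituation, or
history effects beyond linear superposition of overlapping responses.
Passing recovery tests therefore shows the pipeline is correct under the
stated measurement model, not that real recordings satisfy that model.

## Preprocessing

The isosbestic channel is regressed onto the excitation channel by ordinary
least squares over the full session (windowed fitting is a config option; a
constant isosbestic falls back to an intercept-only fit, logged), and
dF/F = (excitation − fitted)/fitted. A fitted reference that is not
strictly positive is an error naming the first offending sample. No
detrending or filtering beyond the isosbestic reference is applied.

z-scoring is either global (whole-session mean/sd) or local (a ±3.2-s
window around each deviant onset, normalized once so the deviant and its
3-back standard share one reference frame; the standard sits at −2.4 s,
inside the window). Unbiased (n−1) sd throughout, recorded in output
metadata. In the pipeline's pairing path, the local mean/sd are estimated
with the anchoring event's own SOA cycle excluded: including the deviant's
enhanced response would deflate every oddball z-value relative to the
many-standards windows and manufacture a spurious standard-vs-control
difference. With the exclusion, the two paradigms' normalizations are
statistically identical under the no-enhancement null.

Epochs are cut on the nearest-sample grid (no sub-sample interpolation),
with the 2-s pre-onset mean stored as the baseline; events whose window
leaves the recording are dropped and logged.

## Features

Component windows are half-open, anchored to onset/offset/change: maximum
in (0, 300] ms after onset, minimum in (0, 800] ms after onset, maximum in
(0, 800] ms after offset, mean over the final min(1 s, duration) of the
stimulus, and maximum in (0, 800] ms after an intensity change (the
drop-positive window mirrors the offset window; configurable, since no
canonical value exists). Ties break to the earliest sample. Amplitudes are
reported as signed z at the extremum; relative amplitudes are measured from
the immediately preceding state (trough minus onset peak, offset peak minus
dip). Under continuous stimulation the response measure is the
peak-to-trough span within one SOA window. The onset/offset ratio clamps
negative inputs at zero to stay in [0, 1] on noisy trials and is undefined
when both are zero. Recording sites are summarized by scalar projection
onto the ventromedial (ML 0.0, DV 8.0) → dorsolateral (ML 8.0, DV 1.5)
axis, in mm.

## Behavior

Sessions are 20-s presentations with the field→condition mapping
re-shuffled every interval, so Start/Goal are conditioned at the condition
level (a field-level index would be meaningless across shuffles):

    PI = Pr(Goal = X | Start ≠ X) − Pr(Goal ≠ X | Start = X)

PI is estimated per animal by default (pooling available). Length of stay
accumulates dwell time per condition, with the pre-first-sample stretch of
each session attributed to the first sampled field so totals conserve the
assay duration. The occupancy heatmap is a 20×20 percent-time grid; the
pseudo-logarithmic display transform (base 10, σ = 0.001) is a rendering
option only. The behavioral simulator draws each session's goal field with
probability proportional to the attraction weight of the condition mapped
to each field; an unbiased walker (equal weights) has PI = 0 in
expectation, and weights (1, 3) give PI = 0.5 for the heavy condition in
closed form.

## Statistics

* **Wilcoxon signed-rank**: zero differences dropped (the common
  convention); exact two-sided p by full enumeration of the signed-rank
  null (dynamic program over doubled midranks, so ties are exact) for
  n ≤ 25, tie-corrected normal approximation with continuity correction
  above.
* **Friedman**: tie-corrected χ² with k−1 degrees of freedom, midranks
  within subjects.
* **Conover post hoc**: the Friedman-conditional t form,
  t = (R_i − R_j) / sqrt{ [2n(A − C)/df] · [1 − χ²/(n(k−1))] } with
  df = (n−1)(k−1), A = Σ r², C = nk(k+1)²/4; Bonferroni multiplies by the
  number of pairs, clipped at 1.
* **JZS Bayes factor** (paired): Cauchy prior (scale 0.707) on the
  standardized effect size, integrated against the noncentral-t likelihood
  by adaptive quadrature at 1e-8 relative tolerance; the tests verify it
  against the independent inverse-gamma mixture (g-integral) form and
  against pingouin. Interpretation thresholds: BF > 3 alternative,
  BF < 1/3 null, else inconclusive.
* **Spearman**: midrank correlation; exact permutation p for n ≤ 9, t
  approximation above.

Bayesian repeated-measures ANOVA and linear mixed-effects motion controls
are out of scope.

## Pipeline and problem sizes

`run_oddball_experiment` simulates a cohort (default n = 21 subjects, a
log-normal inter-subject gain with σ = 0.2), renders an oddball and a
many-standards session per subject, pairs deviants with 3-back standards,
z-normalizes locally, averages peak-to-trough per role, and tests
Dev vs Std, Dev vs MS, Std vs MS with Wilcoxon + Bayes factors. The
default simulated session uses 10–30 deviants per block (two blocks with a
role swap) rather than the full 300, keeping a cohort under a second of
compute while preserving the design's ratio, run constraint and pairing
rule; the full-size design is a config value away. Calibration checks in
the test suite use 800 replicate cohorts for the null rejection rate and
20 for power.

`run_component_characterization` reproduces the component analyses on
synthetic cohorts: grand-average response and per-component stats with
first-two/last-two trial stability, the duration series (offset-positive
is duration-independent by construction, mirroring the null result), the
dynamic-change drop-positive series (monotone in decrement magnitude), and
the SOA series (displaced baseline at onset and attenuated peak-to-trough
at short SOAs, both consequences of incomplete recovery under linear
superposition).

## Numerical notes and limitations

* Latency recovery is limited by the 100-Hz grid (10-ms samples); the
  noise-free end-to-end error is below one sample by construction of the
  calibration, which operates at 1 kHz.
* Amplitude recovery is assessed in dF/F units (extracted z mapped back
  through the stored session normalization, after 2-s baseline
  subtraction), because global-session z depends on total session variance.
  The small onset-positive peak carries an intrinsic upward
  extremum-selection bias of order the averaged noise sd (~10% at the
  default noise floor with 10 trials); the pooled median error across
  components is ~6%.
* Exact drop-positive amplitudes are calibrated at the −40-dB reference;
  other decrements are strictly monotone but not exactly linear after
  superposition with the dip.
* The Wilcoxon exact p at n = 21 is effectively continuous (2²¹ sign
  patterns), so the realized type-I error sits within a fraction of a
  percent of the nominal 5%.
* Degenerate inputs raise typed errors (`DegenerateDataError`,
  `NonPositiveReferenceError`, `InfeasibleDesignError`, ...) rather than
  returning NaNs; the CLI maps them to exit code 1.
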