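# Methods

`fixerp` implements the analysis chain used to study fixation-related
potentials (FRPs) recorded while people walk and navigate with a mobile map:
EEG and eye tracking are recorded by separate devices, synchronized after
the fact, parsed into oculomotor events, deconvolved into overlap-corrected
evoked responses, summarized as component peaks, and modelled with mixed
effects. This note documents the model at each stage, the tunable parameters
and their defaults, what the synthetic cohort generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Synthetic cohorts (`fixerp.synth`)

Every stage is validated against simulated sessions with known ground truth.
One subject is:

1. **A scanpath.** Fixations and saccades alternate. Fixation durations are
   lognormal (median 300 ms, log-SD 0.5) truncated to [80, 2600] ms —
   literature-typical for free viewing; they are modelling assumptions, not
   measured distributions.
   Saccade amplitudes are gamma(shape 2, scale 2.5) degrees; saccade
   duration follows the main sequence (21 ms + 2.2 ms/deg). Each fixation
   draws an AOI label from {Environment 0.78, LM-Abstract 0.11,
   LM-Realistic 0.11}, matching the roughly 900/127/121 epoch-count ratios
   of the study design. Gait steps tick at 1.8 Hz with 5 % jitter.
2. **Evoked structure.** Each fixation adds P1/lambda (90 ms, Gaussian
   SD 16 ms, 4.3 µV multiplied by the saccade-amplitude gain
   `g(a) = 1 + 0.25·ln(1 + a)`), N1 (157 ms, −2.3 µV), P200 (186 ms,
   1.16 µV with per-condition amplitude offsets, default −0.02 µV abstract
   and +0.28 µV realistic, matching published parietal peak-table magnitudes), and a slow
   negative LPC plateau (500–800 ms, −0.28 µV). Each saccade adds a brief
   biphasic spike potential (−8 µV, posterior); each step a broad central
   artifact (5 µV). Kernels are compact-support by construction (Gaussians
   truncated at ±5 SD) so superposition tests can demand exact equality.
3. **Topographies in the average-reference frame.** Component topographies
   are centred to zero mean over the 16-channel montage and scaled so the
   mean weight over the component's anchor cluster is exactly 1. Average
   re-referencing is then a no-op on the signal part, and an injected
   condition offset of +0.30 µV is recoverable as +0.30 µV at the cluster —
   with only 16 channels, non-zero-mean topographies would otherwise be
   attenuated by the reference by tens of percent.
4. **Noise and nuisance.** Per-channel 1/f-power ("pink") noise (SD 3 µV)
   plus white noise (SD 1 µV); small isotropic gaze jitter (SD 0.05°). The
   pink-noise level is the generator's stated calibration: strong enough
   that naive epoch averaging is visibly biased by overlap, while
   deconvolution recovers kernels at roughly 500 fixations per subject.
   A horizontal-eye channel `EyeH` (20 µV/deg times gaze x) stands in for
   the eye-movement IC a real pipeline would extract; gaze timestamps are
   shifted behind the EEG clock by a per-subject offset drawn uniformly
   from [134, 1776] ms, the range observed in mobile coregistration.

What the generator does **not** emulate: volume conduction from realistic
dipoles, blinks and smooth pursuit, non-stationary noise, electrode
impedance drift, clock *drift* (only a constant offset), and real
landmark-viewing cognition. Passing tests therefore demonstrate that the
pipeline's estimators are correct and calibrated under the stated model,
not that any scientific claim about real navigation data is reproduced.

## Synchronization (`fixerp.sync`)

Pearson correlation between the `EyeH` channel and horizontal gaze is
evaluated at every integer-sample lag within ±10 s (unbounded searches can
lock onto spurious distant peaks), with exact per-overlap mean
centering computed via FFT cross-correlation plus cumulative-sum moments.
|r| is maximized because the polarity of an EEG-derived eye component is
arbitrary; ties resolve to the smallest |lag|. No sub-sample refinement is
attempted — lags are reported at the analysis rate (4 ms at 250 Hz), which
matches the ms-level precision the method needs. Gaps are linearly bridged
for the correlation only, never in stored data.

## Oculomotor parsing (`fixerp.oculomotor`)

The adaptive velocity algorithm: 5-sample weighted central-difference
velocity, per-axis robust noise level
`sigma = sqrt(median(v²) − median(v)²)`, elliptic criterion
`(vx/eta_x)² + (vy/eta_y)² > 1` with `eta = 6·sigma`, and a minimum run
length of 4 samples. Velocity at gap samples is forced non-finite so
detection runs can never span a blink. Fixations are the complement of
saccades, split at gaps, filtered to 150–2000 ms **inclusive** (the
exclusion rule is strict-< and strict->), labelled by the majority AOI of
their raw samples (`none` excluded; exact ties go to Environment, biasing
against landmark effects), and annotated with the immediately preceding
saccade's amplitude. A degenerate trace (zero robust SD — e.g., noise-free
piecewise-constant gaze) raises rather than detecting nothing: the
estimator's premise is that fixational noise dominates the velocity
distribution.

## Deconvolution (`fixerp.deconv`)

The continuous EEG is modelled as a superposition of event-locked finite
impulse responses: for each predictor and each lag in its window there is
one free coefficient per channel. Predictors: fixation intercept
(Environment baseline, window −200…+800 ms), treatment dummies for
LM-Abstract and LM-Realistic, a centred cubic B-spline expansion (5 basis
functions, knots at amplitude quantiles) of the prior saccade amplitude, a
saccade intercept (−40…+80 ms), and a step intercept (−200…+600 ms).

Notes on genuinely open choices:

* **Saccade regressor.** The spike potential is saccade-locked, and the
  saccade-to-fixation latency varies with saccade duration; leaving it out
  biases the fixation kernel by ~0.6 µV RMS even without noise. The window
  is deliberately short — just covering the spike — because a wide saccade
  window is nearly collinear with the fixation sticks and inflates
  estimator variance several-fold.
* **Spline centering.** The basis is a partition of unity; each column is
  centred by its value at the reference amplitude (per-subject median), and
  the column largest at the reference is dropped. The intercept is then the
  ERP at the reference amplitude and the spline contributes exactly zero
  there.
* **Solver.** The default solves the normal equations by Cholesky for all
  channels in one factorization, with a reciprocal-condition estimate
  (LAPACK `pocon`) reported in the diagnostics; `solver="lsmr"` runs the
  iterative sparse solver at tolerance 1e-10 and matches the direct path to
  well below test tolerances. Rank-deficient designs (e.g., a condition
  with no events) fall back to a flagged minimum-norm solution with a
  warning. No regularization by default; ridge is exposed for
  ill-conditioned designs.
* **Exclusions.** Fixations without a prior saccade are excluded from the
  design (not imputed); events whose window leaves the recording are
  dropped and counted.

Condition ERPs are reconstructed as intercept (+ dummy) (+ spline at the
requested amplitude) and baseline-corrected over [−200, 0] ms after
reconstruction. Because band-pass filtering is linear and time-invariant,
estimates from filtered data are compared against the ground-truth kernel
passed through the identical zero-phase FIR
(`synth.bandpassed_fixation_response`); the 1 Hz high-pass with a 0.25 Hz
transition has an impulse response of tens of seconds, so the kernel is
zero-padded by 30 s before filtering.

## Components (`fixerp.components`)

Cluster ERPs are unweighted means over occipital {Oz, O1, O2}, parietal
{Pz, P1, P2, POz, CPz}, and frontal {Fz, F1, F2, AFz, FCz}. A single anchor
latency per component is taken from the grand average pooled over subjects
*and* conditions (one anchor per component); each subject-by-condition
waveform is then searched for local extrema of the component's polarity
within ±30 ms of the anchor, keeping the peak *closest* in latency, not the
largest. Local extrema are strict sign changes of the first difference;
plateaus take their midpoint. Windows default to P1 60–130 ms (occipital,
positive), N1 120–200 ms (occipital, negative), P200 150–250 ms parietal /
120–200 ms frontal (positive), and the LPC is a 500–800 ms window mean
(inclusive bounds) rather than a peak. A window without a qualifying
extremum yields `found=False`; such cells are excluded from all statistics,
never imputed.

## Statistics (`fixerp.stats`)

`response ~ AOI * gender + (1 | subject)` by REML, with AOI treatment-coded
against Environment and gender sum-coded (+1 female / −1 male, recorded in
the output). t statistics use containment degrees of freedom — the exact
split-plot strata for this design: between-subject terms (intercept,
gender) against subjects (`n_subjects − 2`), within-subject terms (AOI and
its interactions) against the within-subject error
(`n_obs − n_subjects − 4`). Satterthwaite-type corrections are not
available in the backing library; for balanced random-intercept data the
containment df equal the exact ANOVA df, and a null-calibration simulation
(200 zero-effect cohorts) verifies that the rejection rate at alpha = .05
stays inside its binomial interval at the cell counts used here. Pairwise
condition contrasts within each gender use estimated marginal means from
the fixed effects with Tukey correction over the family of three
comparisons (studentized-range distribution, k = 3) at the within-subject
df. With the random-intercept variance
at zero (balanced data), the fixed effects coincide with OLS, which the
tests verify; an lme4 fit of the identical model serves as an independent
cross-check of estimates and standard errors.

## Pipeline (`fixerp.pipeline`)

Per subject: band-pass 1–30 Hz (zero-phase Hamming FIR, transition widths
25 % of each band edge) at the acquisition rate, downsample to 250 Hz,
average-rereference the scalp channels (the `EyeH` channel is filtered and
resampled but excluded from the reference), estimate and apply the gaze
lag, upsample gaze to 250 Hz, detect events, build the design, fit, and
reconstruct cluster ERPs per condition. Step events are taken from the
recording's step annotations, mirroring a pipeline that derives footfalls
from a dedicated source rather than from gaze. Cohort level: grand-average
anchoring, peak extraction, a peak-summary table (mean amplitude/latency
and n per component × condition), amplitude and latency mixed models per
component, and Tukey pairwise tables. All randomness flows from one master
seed (per-subject seeds spawned via `SeedSequence`), so runs are exactly
reproducible; a manifest records versions, seed, and parameters. Stages are
re-run unconditionally — determinism is carried by seeds, not caching.

The average reference is computed over all delivered scalp channels; the
study interpolated rejected channels first, but channel rejection and
interpolation are out of scope here, so the reference set is simply the
montage.

## Problem sizes

Validation uses 60-s sessions for synchronization (20 subjects), 210-s
sessions (~500 retained fixations) for overlap correction (10 subjects) and
effect recovery (10 replicate cohorts of 12 subjects), 200 reduced-scale
simulations for null calibration, and 100 random traces for the detector
oracle. These sizes give the recovery checks comfortable margins while
keeping a full validation run in the minutes range on one core.

## Known limitations

* Constant-offset synchronization only; clock drift is out of scope, as in
  the source analysis.
* The frontal P200 in the generator is the frontal projection of a single
  P200 kernel (plus the N1 polarity reversal), so its latency is not
  independently controllable.
* ICA-based artifact removal, bad-channel handling, and spectral cleaning
  are out of scope; the generator supplies the eye nuisance channel and
  step events directly.
* The residual-df p-values are an approximation; they are validated by
  simulation at the sizes used here, not claimed exact.
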