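# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated against — including what passing tests do and
do not establish about real recordings.

## Pipeline overview

1. **Stimuli** — 80 arithmetic problems (40 subtractions, 40
   multiplications) in four blocks; *small* problems (both operands ≤ 10)
   proxy fact retrieval, *large* problems proxy procedures, and large
   subtractions always require borrowing (subtrahend > ones digit of the
   minuend).  The packaged TSV fixture is validated against these design
   constraints rather than trusted blindly.
2. **Preprocessing** — bad-channel detection → common average reference →
   artifact-segment masking → ICA-based ocular removal.
3. **ERD/ERS** — per-trial/channel median band power in baseline
   [−1.25, −0.25) s and activity [0, RT) windows; per-condition medians
   across trials; `(A − B)/B × 100`; ROI means.
4. **Behavior** — strategy-report consistency filter, Cohen's κ, accuracy
   and RT summaries.
5. **Inference** — GLMMs (RT, accuracy) and LMMs (ERD/ERS per band) with a
   participant random intercept; estimated marginal means and
   Tukey-corrected pairwise contrasts.

Trials with inconsistent or unknown strategy reports are excluded *before*
vertical averaging, and all RT/ERD-ERS analyses use correct answers only.

## Frequency bands and filtering

Bands: theta 3–6 Hz, lower alpha 8–10 Hz, upper alpha 10–13 Hz.  Each
band-pass is a Hamming-window FIR applied by centered convolution (odd
length, symmetric taps → exactly zero phase).  The half-amplitude (−6 dB)
cutoffs sit *on* the printed band edges, so the two alpha bands tile the
spectrum and overlap only at the shared 10 Hz edge.  Transition bandwidth
is 25% of each edge frequency with a 1 Hz floor; filter length follows the
Hamming rule 3.3/Δf using the narrower transition (theta ≈ 3.3 s kernel,
upper alpha ≈ 1.3 s).

This cutoff convention matters: placing full gain at the band edge (the
other common convention) lets the 9 Hz lower-alpha rhythm pass the
upper-alpha filter at ≈ 0.5 amplitude, and cross-band leakage then biases
adjacent-band ERD/ERS estimates by several percentage points.  With
cutoffs at the edges, cross-band gain is < 0.03 amplitude.

Windows are half-open with the onset sample belonging to the activity
window.  The filter's step response rings through the early activity
window (the theta kernel spans 3.3 s), which deflects *single-trial*
median power estimates by up to ~±4 percentage points for 2 s windows;
the deviation depends on the oscillation's phase and cancels under
vertical averaging across trials, so condition-level estimates are
accurate to well under 1 point for the trial counts of this design (and
single-trial estimates recover that accuracy once the window exceeds
roughly the kernel length).

## Cleaning surrogates

The reference workflow made bad-channel, artifact, and component decisions
by visual inspection.  This package substitutes automated, deterministic
rules with thresholds in `PreprocConfig`:

- **Flat channels**: robust (MAD-based) amplitude spread < 0.5 µV.
- **Noisy channels**: robust z > 5 of log *high-frequency* power (variance
  of the first difference).  High-frequency power is used deliberately:
  total variance would flag every frontal channel on a blinky recording,
  whereas channels carrying ordinary ocular signal are healthy.
- **Artifact segments**: any good channel above 400 µV absolute or a
  200 µV sample-to-sample jump, padded by 250 ms and merged.  The 400 µV
  level is chosen above ordinary blink amplitude on purpose — if blinks were
  masked, the ICA step could never learn the ocular component.  All
  downstream windows ignore masked samples; a trial is unusable when less
  than half of either window survives.
- **Ocular ICA**: FastICA estimated on a 1 Hz high-passed copy of the
  unmasked data (decimated ×4 for speed; the unmixing applies to the full
  recording).  The number of components equals the numerical rank of the
  data — one less than the number of good channels after common-average
  referencing; requesting the full channel count would make the whitening
  singular.  A component is removed iff (i) |correlation| of its time
  course with the Fp1/Fp2 mean ≥ 0.6 **and** (ii) its < 3 Hz share of
  spectral power (up to 40 Hz) ≥ 0.5.  Flagged components are zeroed and
  the original (unfiltered) data back-projected, so retained activity
  passes through exactly.  The decomposition is deterministic (fixed seed);
  an exhausted iteration budget is recorded as a warning in the cleaning
  report, while a non-finite unmixing raises an error with diagnostics.
  ICA weights are estimated once per session.

## Mixed-effects models

All models use sum-to-zero factor coding, so main effects remain
interpretable in the presence of interactions (Type-III-style testing),
and a single random intercept per participant.

- **Response time**: inverse-Gaussian GLMM with identity link, fit by
  maximizing the marginal likelihood with 20-node Gauss–Hermite quadrature
  over the random intercept (statsmodels offers no frequentist GLMM for
  this family).  Per-term χ² statistics are likelihood-ratio tests, each
  term removed from the full model in turn.  If the fit fails, the model
  falls back — with a logged warning — to a Gaussian mixed model on log RT
  with LRT-based χ² tests.
- **Accuracy**: binomial GLMM (logit link), same machinery.  Complete or
  quasi-complete separation (no response variation, or |logit coefficient|
  > 10) is reported in the fitted model's warnings, never silently dropped.
- **ERD/ERS**: one Gaussian LMM per band (statsmodels `MixedLM`, REML) with
  the full operation × strategy × ROI × hemisphere factorial.  Per-term
  Wald F statistics use denominator degrees of freedom
  `n − p − (g − 1)` — observations minus fixed-effect columns minus
  participant degrees of freedom — the standard small-sample approximation
  for balanced within-participant designs (992 rows and 32 columns at 31
  participants give 930 denominator df).  A singular fit triggers a logged
  refit without the four-way interaction.
- **Post-hocs**: estimated marginal means average model predictions over a
  balanced grid of the remaining factors; all C(k, 2) pairwise contrasts
  are adjusted with the studentized-range (Tukey) distribution at the
  model's denominator df (normal/z for the GLMMs).  95% confidence
  intervals accompany every marginal mean.  For the binomial model the
  means are on the logit scale.

Type-I error of every term is verified by simulation: 200 null replicates
of a 10-participant design keep each term's rejection rate at α = 0.05
within [0.02, 0.09].  The three band models are fit separately with no
cross-band correction, matching the analysis design this pipeline
re-implements.

## Synthetic data: what it emulates

Per participant the generator produces one continuous 32-channel, 512 Hz
recording (trials concatenated with the task's timing: 1.5 s fixation,
problem until response, ~2 s verbal report, 1.5 s blank) plus a trial
table.  Components:

- **Background**: 1/f pink noise, 10 µV SD per channel, independent across
  channels, spectrum flattened below 0.5 Hz.
- **Oscillations**: one carrier per band (4.5, 9, 11.5 Hz — inside each
  passband) on all ROI channels with per-channel random phase (a common
  phase would be annihilated by the common average reference).  The
  amplitude steps from a_B = 40 µV during fixation to
  a_A = a_B·√(1 + target/100) during the response interval, so the
  configured target *is* the closed-form ERD/ERS.  The oscillation starts
  2.5 s before onset and outlasts the response by 0.5 s so that filter
  edge effects stay outside the analysis windows.  Default targets
  (by strategy, uniform over ROIs): theta +22/+11, lower alpha +3.5/−1.8,
  upper alpha −8.8/−11.5 (retrieval/procedure).
- **Ocular artifacts**: a stereotyped ~300 ms biphasic blink (250 µV at
  Fp1/Fp2, frontally dominated fixed topography, ~10/min) and a horizontal
  saccade source (smoothed telegraph signal, F7/F8 antisymmetric); a third
  slow-drift source is available.  Blink times are kept as ground truth so
  tests can measure suppression directly.
- **Behavior**: inverse-Gaussian RTs with per-condition means
  (2.07, 2.18, 6.44, 10.05 s) and shapes (8, 8, 10, 12 — variance
  μ³/shape, giving realistic right skew), Bernoulli correctness (0.980,
  0.978, 0.910, 0.915), and verbal reports that disagree with problem size
  at rate 292/2480 (plus 32/2480 "unknown"), calibrated to the reference
  cross-tabulation in `REFERENCE_STRATEGY_CROSSTAB`.

Oscillation and artifact amplitudes are not reported quantities anywhere;
they are chosen once for realistic signal-to-noise and testability.  At
these defaults an 8-participant pilot recovers all six (band × strategy)
targets within 0.5 percentage points; recovery degrades gracefully as
`osc_amplitude` shrinks toward the in-band noise floor (the additive noise
power dilutes the power ratio toward zero — at a_B = 25 µV the theta bias
is about −1 point).

**What the generator does not emulate**: volume conduction beyond a fixed
mixing matrix, spatially correlated background activity, non-stationary
rhythms, muscle/EMG artifacts, electrode drift or re-gelling, and real
children's trial-to-trial variability in oscillatory engagement.  Passing
the recovery tests therefore shows the *estimator chain* is unbiased under
the assumed signal model, not that effect sizes from real recordings are
unbiased.

Null calibration of the models runs at the level the models consume
(trial-level behavior, record-level ERD/ERS tables) rather than through
200 full EEG simulations; problem sizes for those replicates (10
participants, 20 trials per cell) are the package's scaled-down
calibration design.

## Degenerate inputs and tie-breaks

- A condition group with no usable trials, or median baseline power of 0,
  yields a *missing* record (never a fabricated value); an ROI whose
  channels are all bad yields a missing record with a warning.
- ERD/ERS values are bounded below by −100% whenever A ≥ 0 and B > 0.
- Quartiles (RT summaries) use linear interpolation; RT summaries pool
  trials across participants so min/max refer to individual problems,
  while accuracy is averaged within participants first.
- Events round-trip through TSV at millisecond precision; EDF output is
  16-bit with 1 s records (a final partial record is zero-padded with a
  warning).
- When several band-effect specifications match a condition, the most
  specific one (most non-wildcard fields) wins.

## Known limitations

- The channel→ROI map reconstructs the montage grouping from the ROI names
  and electrode geometry; it is configurable (`roi_map`) because the
  original assignment is not published as text.
- The inverse-Gaussian GLMM's identity link admits negative cell-mean
  excursions during optimization; a soft barrier keeps μ positive, which
  can slow convergence on pathological data (the log-RT fallback then
  engages).
- Tukey adjustment assumes the marginal-means covariance is well estimated;
  with very few participants (< 5) the GLMM covariance can be unstable.
- The EDF writer targets interchange with standard readers (tested against
  MNE's); it writes the EDF subset this pipeline needs (continuous signals,
  uniform sampling rate), not annotations.
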