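# Methods

## The tracking-error statistic

A pursuit-tracking trial records three aligned 2-D time series at 60 Hz
for 45 s: the target's Lissajous path (x at 0.075 Hz, y at 0.1 Hz), the
deterministic cursor-perturbation Lissajous (0.14 / 0.21 Hz), and the
participant's cursor. Tracking error is defined through residuals
rather than raw distance-to-target so that systematic, non-erroneous
components of the cursor path — a response gain different from 1, a
constant visuomotor delay, the injected perturbation — do not count as
error.

Per axis, the cursor position is regressed (OLS, intercept always
included) on the target curve, the perturbation curve, and the Hilbert
quadrature of each. A sinusoid and its quadrature span every
phase-shifted copy of that sinusoid, so a pure tracking delay is
absorbed by the design rather than scored as error. The residual series
`ErrX`, `ErrY` combine pointwise into `ErrR(i) = sqrt(ErrX(i)² +
ErrY(i)²)`, which is segmented into consecutive sub-trials of one
quarter of the target's y-period — 2.5 s, i.e. 150 samples, 18
sub-trials per 45 s trial — and averaged within each segment. Trailing
partial segments are discarded.

Sub-trial means are the analysis unit everywhere downstream:

- `ΔErr` — mean over paired sub-trials of (two-pole − three-pole)
  error; negative values favour the two-pole montage.
- individualised stimulus — the non-sham (stimulus, montage) pair with
  the smallest mean error for a participant; exact ties break by bank
  order GVS1→GVS8, then two-pole before three-pole.
- `PI_GVS = 100·(ErrR_SHAM − ErrR_GVS)/ErrR_GVS` and
  `PI_Ind = 100·(ErrR_GVS − ErrR_Ind)/ErrR_Ind`, with condition errors
  averaged across the two montages before entering the formulas. The
  individualised error is, by default, the single-montage minimum (the
  pair actually selected); a switch averages the chosen stimulus across
  montages instead, for the reading in which every quantity is
  montage-averaged.
- Repeated sham trials are averaged sub-trial-wise before any
  comparison, so each condition contributes one mean-error vector.

## Design choices in the error pipeline

- **Regressor set.** The default design removes both deterministic
  curves (target and perturbation) and their quadratures; the
  perturbation is a known nuisance injected by the task, and leaving it
  in would score task hardware as participant error. A `"target"`
  switch keeps the narrower design for sensitivity analyses.
- **Per-axis regression.** x-cursor on x-regressors, y-cursor on
  y-regressors; no cross-axis terms.
- **Hilbert transform on the full trial.** Quadratures are computed on
  the complete 45 s series before segmentation, avoiding per-segment
  edge artefacts. Because the trial holds a non-integer number of
  x-axis target periods (3.375), the discrete analytic signal carries
  some spectral leakage: a time-shifted noiseless cursor leaves
  residuals of order 1–3 % of the target amplitude rather than zero.
  The quadrature columns still suppress lag-induced error by more than
  a factor 3 relative to a design without them, and the effect is
  common to all conditions of a participant, so condition contrasts are
  unaffected to first order.
- **Rank-deficient designs** drop collinear columns right-to-left with
  a logged warning instead of failing.

## The synthetic cohort generator

The simulator replaces the human participant with a descriptive model:

    cursor(t) = gain · target(t − lag) + perturbation(t) + ε(t)

with `ε` zero-mean Gaussian noise, low-pass filtered (first-order IIR,
default cut-off 2 Hz) so residuals are autocorrelated the way smooth
human motor error is, and scaled so its stationary SD equals
`base_noise_sd × multiplier(stimulus, montage)`. The effect map of
multipliers is the planted ground truth: stimulation conditions act
*only* through it, because the analysis measures effects on error
magnitude, not a biomechanical transduction path (the stimulus waveform
never enters the cursor equation).

Cohort defaults mirror the crossover design the pipeline targets: 10
participants × 2 montages × (8 AM stimuli + 2 sham trials), 45 s trials
at 60 Hz, unit target amplitude and 0.25 perturbation amplitude.
Per-participant parameters are drawn once per participant from an
independent random substream (so adding participants never perturbs
existing data): gain lognormal around 1 (sd 0.05), lag uniform on
0.1–0.3 s (a typical visuomotor delay range), noise SD lognormal around
0.1 screen units (cv 0.2) — roughly 10 % of the target amplitude, a
realistic tracking-error scale. Between-participant heterogeneity of
stimulus response is modelled as lognormal jitter (default sd 0.15) of
the non-sham multipliers, which lets individualised stimuli differ
across participants; explicit per-participant effect maps can be
supplied instead for planted-recovery studies.

What the simulator does **not** emulate: tremor spectra or any
disease-specific kinematics, vestibulo-motor transduction physiology,
learning or fatigue across trials, and non-stationary noise within a
trial. Passing tests on synthetic cohorts therefore demonstrate that
the pipeline recovers planted effect structure under its own generative
assumptions — not that those assumptions describe any particular
patient population.

## Statistical layer

- **Montage contrast.** `mean_err ~ montage` with crossed random
  intercepts for participant and sub-trial index (variance components
  on a single grouping), REML estimation, fixed-effect p from the
  large-sample normal approximation. Positive estimates mean larger
  error in the three-pole montage. With a single participant in scope
  the subject term is dropped (only sub-trials repeat). A variance
  component estimated at its zero boundary is accepted as a legitimate
  fit; only genuine failures (non-finite estimates) trigger the
  fallback to a subject-only random intercept, with a logged warning.
  A 500-cohort null simulation puts the empirical type-I error of this
  contrast at ≈ 0.05–0.06 at α = 0.05.
- **Sham vs individualised.** Paired Wilcoxon signed-rank, exact null
  distribution up to 25 pairs (normal approximation with continuity
  correction above, or when ties make the exact distribution
  unavailable), zero differences dropped. The reported estimate is the
  median paired reduction (sham − individualised). Note the signed-rank
  p is invariant under increasing *affine* transforms of both pair
  members but not under arbitrary monotone maps, which can re-rank the
  absolute differences.
- **FDR.** Benjamini–Hochberg step-up adjustment. The eight
  per-stimulus montage contrasts form one family; per-participant test
  families are adjusted within participant.
- **Error bars for medians** use a seeded bootstrap (default 1000
  resamples).

## Stimulus synthesis

AM stimuli are synthesised as the suppressed-carrier product
`s(t) = A · sin(2π f_env t) · sin(2π f_car t)` (an optional modulation
depth m < 1 re-introduces a carrier component). Synthesis defaults to
600 Hz sampling — at least twice the highest carrier (145 Hz) — and
emits an `AliasingWarning` whenever the requested rate is below the
carrier's Nyquist rate, including the task's historical 60 Hz
acquisition rate. The perception threshold is a single ascending
staircase (base 0.1 mA, steps of 0.1 mA) and the stimulation amplitude
is 90 % of it, held separately per montage.

## Numerical and problem-size choices

- OLS via `numpy.linalg.lstsq`/pinv; residual orthogonality to the
  design holds to ~1e-10 relative. Trial CSVs serialise floats with 17
  significant digits and are parsed in round-trip mode, so numeric
  content survives a write/read cycle bit-exactly.
- Monte-Carlo studies in the test suite use 100 cohort seeds for
  planted individualised-stimulus recovery (scored against the
  simulator's recorded ground truth) and 500 cohorts for the
  mixed-model null calibration; both use the default cohort size of 10
  participants.
- Degenerate inputs: sham-only data sets yield a one-row improvement
  report (0 % over sham) and no individualised choices; all-zero paired
  differences give p = 1 with a warning; a staircase that never reaches
  perception raises a non-convergence error after a configurable step
  budget (default 100).

## Known limitations

- The quadrature-regression lag absorption is exact only for
  integer-period sinusoids; see the leakage note above.
- The mixed model treats sub-trial means as conditionally Gaussian;
  they are means of folded-Gaussian magnitudes, which is adequate at
  150 samples per sub-trial but untested for much shorter segments.
- The improvement percentages are ratios of noisy means and are biased
  upward for small denominators; no small-sample correction is applied.
- Individualised selection is a raw arg-min: with 18 candidate
  conditions per participant it capitalises on noise when true effects
  are small, and the reported individualised improvement inherits that
  winner's-curse optimism (visible in the sham row of any
  null-effect improvement report).
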