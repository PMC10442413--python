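# Methods

This note documents the models, estimators and numerical choices behind
`crowdeda`, and what the synthetic-data validation does and does not show.

## Signal model

Skin conductance `y(t)` (µS, sampled at 32 Hz on the palm) is modelled as

    y(t) = tonic(t) + (h * q)(t) + e(t)

* **tonic** — the slowly varying skin conductance level (SCL): baseline
  level, slow drift, and condition-dependent shifts;
* **q ≥ 0** — a sparse non-negative sudomotor driver; each burst produces a
  skin conductance response (SCR);
* **h** — the biexponential (Bateman) SCR kernel
  `h(t) = gain (e^{-t/τ_d} - e^{-t/τ_r})` with defaults τ_r = 0.7 s,
  τ_d = 2.0 s, the conventional SCR shape constants. The kernel is used
  with unit peak gain, so driver mass is on the scale of SCR peak
  amplitudes;
* **e** — measurement noise.

## Preprocessing

A first-order Butterworth low-pass at 0.6 Hz removes sensor noise. It is
applied forward–backward (zero phase) so features stay aligned with
condition intervals; the two passes square the single-pass magnitude
response, making the effective gain at the nominal cutoff 0.5 instead of
1/√2. Downsampling uses a zero-phase 8th-order Butterworth anti-alias
filter at 0.45 of the output rate.

Artifact control is a deterministic two-stage screen in the spirit of
rule-based quality assessment for wrist-worn EDA. Per-sample rules flag
conductance outside [0.05, 60] µS, one-sample slopes above 10 µS/s, and
windows of 5 s with range below 10⁻⁴ µS (flatlines). When an accelerometer
channel exists, a flagged interval is marked *accelerometer-coincident* if
accelerometer activity exceeds the recording median + 3 MAD within ±2 s —
a robust, parameter-light burst detector. A segment is excluded when more
than 10 % of its samples are flagged or it contains a flat/zero run of at
least 5 s. The original workflow resolved flagged intervals by visual
inspection; the fixed numeric verdict replaces that step to make exclusion
reproducible and testable. All thresholds are configurable
(`ArtifactRules`); they are stated conventions, not estimates of any
published rule table.

## Decomposition

The tonic/phasic split solves the convex program

    minimize  ‖y − h*q − Bc‖² + λ‖q‖₁ + µ‖D₂ c‖²   subject to  q ≥ 0

with `B` a cubic B-spline basis on a 10 s knot grid plus a linear trend and
`D₂` the second-difference (curvature) penalty on the spline coefficients.
Because `q ≥ 0` the L1 term is linear and the program is a strictly convex
bound-constrained QP; it is solved with L-BFGS-B using the exact gradient,
the kernel convolution applied directly (FFT for long segments). The
residual is defined as `y − tonic − phasic`, so the additive identity is
exact by construction. Ties at phasic plateau peaks resolve to the earliest
sample. Decomposition runs separately per condition segment.

**Sparsity weight.** λ = 0.05 by default. The weight acts as a soft
threshold on driver mass: too small (≲10⁻³) and the driver mops up
filtered-noise wiggle and spline edge error, producing spurious
sub-0.05 µS events (measured false-discovery ≈ 0.4); at 0.05 the recovery
benchmark reaches sensitivity 1.0 with FDR ≈ 0.01 while shrinking true
amplitudes by only ~λ/(2‖h‖²) ≈ 10⁻³ µS. Scaling the input by c together
with λ scales all components by c (homogeneity), so the default is
appropriate across the physiological µS range. µ = 10⁻² and the 10 s knot
spacing control tonic stiffness; both are configurable and reported
alongside results.

SCR peaks (Ns.SCRs) are local maxima of the phasic trace with
trough-to-peak amplitude strictly greater than 0.01 µS (amplitude measured
from the preceding local minimum — the standard trough-to-peak convention).

## Features

Per subject × condition segment: `mean_scl` (mean tonic, µS),
`nsscr_count`, `mean_amplitude` (µS; 0 when no events, keeping
repeated-measures tables complete), and `edasymp` — power of the
mean-removed signal in the 0.045–0.25 Hz band after downsampling to 2 Hz,
estimated by Welch PSD (Blackman window, 128-sample segments, 50 %
overlap) and integrated by the trapezoid rule. Raw µS² units are reported
(area under the PSD); a total-power-normalized variant is available. The
filtered full signal is used (not the phasic component only); this is
configurable.

**Baseline z-standardization.** Between-subject comparisons use each
subject's own resting baseline: baseline statistics are estimated from
non-overlapping windows of the baseline segment (default 30 s), and each
feature value becomes `(x − m_s)/sd_s`. 30 s windows (not shorter) are used
because the band-power feature needs enough samples per window for a
spectral estimate (its Welch segment length shrinks to the window), and
count features are rescaled from window rate to segment duration so scales
match. A zero or undefined baseline SD is an error naming subject and
feature — never silently imputed.

## Design quantities

The oval experiment sets density by occupant count on a closed loop of
circumference 14.97 m; per-person gross space is `circumference / n` and
net space subtracts an average human body depth of 28.8 cm. **Rounding
convention:** gross space is rounded (half-even) to 2 decimals *before*
subtraction and the result rounded again. This round–subtract–round order
is the only convention that reproduces the published table (24 occupants:
0.62 − 0.288 = 0.332 → 0.33, whereas subtract-first gives 0.336 → 0.34).
Arithmetic uses decimal, not binary floats. Net space maps onto Hall's
proxemic zones with the conventional metric cut-offs (near/far intimate
0.15/0.45 m, personal 0.75 m, near/far social 1.2/2.1/3.6 m, public
beyond), half-open on the upper bound; zone assignment from *net* space
reproduces every published condition→zone statement, which gross space
would not. Metronome pacing covers one marker spacing in two beats:
`spacing = v · 2 · 60/bpm`.

## Statistics

* **Normality screen** — Lilliefors-type KS statistic (normal with
  estimated mean/SD); since estimation changes the null distribution, the
  p-value is a seeded Monte-Carlo tail probability (1000 simulated samples,
  seed 1234 by default) for reproducibility.
* **Test selection** — per feature, each condition cell is screened at
  α = 0.05; any rejection routes the feature to the Friedman test,
  otherwise to the repeated-measures ANOVA. The granularity (per cell) and
  α are explicit choices.
* **Friedman** — mid-ranks with tie correction. The χ²(k−1) reference is a
  large-sample approximation that can miss the exact tail by > 0.1 for a
  handful of subjects, so for small tables (k!ⁿ within a 5·10⁵ enumeration
  budget) the p-value is computed exactly by enumerating within-row rank
  permutations; larger tables use χ².
* **RM-ANOVA with Greenhouse–Geisser correction** — one-way within-subject
  F; ε from the double-centered condition covariance, clamped to
  [1/(k−1), 1]; both df multiplied by ε (ε = 1 exactly at k = 2).
  Verified against an independent implementation (pingouin) in the tests.
* **Post-hoc** — paired t-tests on raw values for all k(k−1)/2 pairs,
  Bonferroni-adjusted, capped at 1. Raw-value (not rank-based) pairwise
  tests after a Friedman omnibus are unconventional but match the source
  workflow's wording; the matrix is symmetric with unit diagonal.
* **Moderation mixed model** — `z-feature ~ speed * moderator` with a
  random intercept per subject (no random slopes; the structure is not
  identified by the small designs targeted). t statistics use residual df
  (n − rank(X)); a Satterthwaite approximation is not available in the
  underlying fitter. A singular random-effects fit falls back to OLS with
  a warning — with balanced designs the fixed effects are unaffected.
  These are moderation (interaction) models; no causal mediation analysis
  is implied by the "mediator" terminology.
* **Effect size** — Cohen's d with (n−1)-weighted pooled SD.
* Complete cases only throughout; no imputation.

## Synthetic cohorts

The generator emulates the statistical structure of the two studies, not
the physiology of any subject:

* baseline SCL per subject ~ Normal(6, 3) µS truncated at 0.5 µS
  (magnitudes in the range of the published group means);
* slow linear drift (slope ~ Normal(0, 0.001 µS/s));
* per-condition tonic offsets; the study-shaped cohorts use the published
  group-mean differences as the planted pattern (walking-speed study:
  free-speed most arousing; oval study: monotone-ish rise over the 8
  densities spanning ≈ 2.3 µS);
* idiosyncratic per-subject, per-condition tonic scatter
  (`subject_effect_sd`, default 0.3 µS), representing run-to-run state
  changes (rest breaks, electrode settling). This term matters: without
  it the null cohort's within-subject covariance is rank-1 (drift only),
  a degenerate structure no real cohort exhibits and one for which the
  GG correction is measurably liberal;
* SCR events from a Poisson process with a 3 s minimum spacing. The count
  is drawn exactly Poisson(rate·duration); given the count, times are
  order statistics of uniforms on the spacing-shrunk interval, preserving
  the count law while enforcing the gap. 3 s (not less) because the
  0.6 Hz zero-phase low-pass merges phasic peaks closer than ~2 s, which
  would make planted events unresolvable by trough-to-peak detection;
* amplitudes ~ Normal(0.3, 0.1) µS truncated at 0.05 µS; white Gaussian
  noise (0.01 µS);
* optional artifacts (flatline, 5 µS spike step, dropout-to-zero) with a
  synchronized accelerometer burst for the motion-like kinds;
* a single integer seed threaded hierarchically (cohort → subject →
  condition) through `numpy` `SeedSequence`, so identical seeds give
  bit-identical cohorts.

**What passing tests show — and do not.** Recovery and power results on
these cohorts validate the *implementation* (the estimators recover what
was planted, at the planted magnitudes, with controlled error rates). They
do not validate the generator against real palmar EDA: no gait-cycle
coupling, temperature/humidity effects, non-Gaussian noise, or
physiologically detailed sudomotor dynamics are modelled, and the planted
effect magnitudes follow the published group means rather than any fitted
model. Real-data statistics from the original studies are therefore not
reproduction targets.

## Problem sizes

Validation workloads are sized for a single CPU: the SCR recovery
benchmark uses 50 recordings of 60 s decomposed on an 8 Hz grid; the
power/type-I study uses 100 cohorts per arm of 44 subjects × 8 conditions
with 72 s segments simulated at 8 Hz and decomposed at 2 Hz (SCR kernels
and the sympathetic band live well below 1 Hz, so these grids lose
nothing that those analyses need); the mixed-model recovery uses 100 runs
of 100 subjects × 4 speeds. The full-rate path (32 Hz recordings, 3-min
conditions) is exercised by the study-shaped simulators and the examples.

## Known limitations

* The decomposition weights are defaults, not estimates; strongly
  overlapping SCRs (< 3 s apart) merge into single detected events.
* The exclusion verdict replaces human visual inspection; borderline
  segments a human might keep are dropped deterministically.
* GG-corrected RM-ANOVA remains approximate under extreme sphericity
  violation; the Friedman route is the guard, triggered by the normality
  screen only.
* Band power on short segments (< 64 s at 2 Hz) is undefined by design;
  the baseline-window variant shrinks the Welch segment instead, trading
  frequency resolution for availability.
* Baseline z-scores on synthetic cohorts come out large in magnitude:
  the simulated resting tonic is nearly constant, so windowed baseline
  SDs are a few hundredths of a µS and planted ~2 µS condition offsets
  are many resting-SDs. Real resting baselines wander (habituation,
  thermoregulation) and yield moderate z values; the convention, not its
  synthetic-scale output, is what transfers to real data.
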