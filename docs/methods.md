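# Methods

## Scope and data model

The package analyses *locomotion episodes*: segments of tri-axial trunk
acceleration (100 samples/s, ±6 g range, units of g) already classified
as walking by an upstream activity detector. Episodes carry subject /
week / day labels. The analysis chain is

episodes → axis realignment → 10 s epochs → gait characteristics →
weekly medians per subject → variance components across two weeks →
required participants for a paired pre/post trial.

Activity classification itself, step-event detection and percentile
summaries other than the median are out of scope.

## Signal model (synthetic episodes)

`signal_sim` generates gait-like acceleration with known ground truth.
With stride frequency f_stride (strides/s) and step frequency
f_step = 2·f_stride:

- VT and AP are cosine series at multiples of f_step (vertical and fore-aft
  movement repeat every step); ML is a cosine series at multiples of
  f_stride (lateral sway alternates left/right, so it repeats per stride).
- An `asymmetry` fraction moves ML power from stride to step frequency,
  imitating left–right asymmetric gait (total ML power preserved).
- The stride phase carries Brownian jitter: increments
  N(0, σ²·f_stride·dt) per sample, accumulating variance σ² per stride
  (σ = `phase_jitter_sd`, radians/√stride). The continuous random walk
  roughens the waveform at every time scale, which is what lets this one
  knob degrade stride regularity, local dynamic stability *and* sample
  entropy together; a jitter interpolated only between stride boundaries
  leaves the waveform locally smooth and sample entropy (templates span
  30 ms at 100 samples/s) essentially blind to it.
- 1 g of gravity on VT, an optional yaw/pitch/roll mis-orientation
  rotation applied last, additive white sensor noise, hard clipping at
  the ±6 g sensor range (clipped samples are logged).

Defaults (amplitudes ≈ 0.03–0.22 g across the first three harmonics,
f_stride = 0.9, noise 0 unless requested) produce signals in the
amplitude range of older-adult walking. The generator does **not**
emulate turning, stops, stairs, amplitude variability between strides, or
non-stationary wear artifacts — passing tests show the estimators are
correct under the stated model, not that real recordings are this clean.

## Axis realignment

Sensor axes rarely coincide with anatomical axes. Realignment is
two-stage: (1) the episode-mean acceleration (gravity) is rotated onto
+VT (Rodrigues rotation; episodes whose mean vector is below 0.1 g are
rejected as non-wear/free-fall); (2) the residual rotation about the
vertical is resolved by minimizing ML power at the detected step
frequency — in left-right symmetric gait ML concentrates at the *stride*
frequency, so any step-frequency power in ML is leaked AP signal. The
objective is sinusoidal in twice the yaw angle; a 1° grid scan brackets
the global minimum (ties broken toward the smallest |yaw|) and
golden-section search refines it. Gravity (the column means) is then
subtracted. On noiseless synthetic episodes arbitrary rotations are
undone to < 1e-6 g.

## Gait characteristics

All characteristics are computed per 10 s epoch (non-overlapping windows;
the trailing remainder is discarded; episodes shorter than 10 s are
skipped). Step frequency is the peak of the combined VT+AP periodogram in
1.0–4.0 Hz (parabolic refinement), covering older-adult cadence; stride
time is the highest unbiased-autocorrelation peak of VT within ±25% of
twice the step time, refined by parabolic interpolation. Epochs whose
stride-autocorrelation peak falls below 0.15 are flagged non-gait: the
threshold sits far below plausible gait values (≳ 0.5) and above the
≈ 3/√N fluctuation scale of aperiodic noise, for which a literal
"peak > 0" rule would fail.

- **Walking speed / stride length.** VT acceleration (→ m/s²) is
  double-integrated in the frequency domain, restricted to
  0.1 Hz–3·f_step (frequency-domain integration avoids the drift that
  time-domain cumulative sums accumulate over a 10 s epoch). The mean
  per-step peak-to-peak vertical excursion h feeds the inverted-pendulum
  step length 2·√(2ℓh − h²) (leg length ℓ, default 0.9 m);
  speed = step length × f_step.
- **Dispersion.** Per-axis SD and range, in m/s² by default (a config
  switch selects g).
- **Stride regularity.** Unbiased autocorrelation at the stride lag
  (local maximum within ±10%), clipped to [−1, 1].
- **Spectral peak.** Welch spectrum (Hann, 5 s segments, 50% overlap)
  normalized to unit power. The dominant amplitude is the power fraction
  in the peak bin, its immediate neighbours (window leakage always spreads
  a tone there) and any contiguous bins above half the peak height; the
  width is that region's span in Hz.
- **Index of harmonicity.** P(f₀)/Σₖ₌₁⁶P(k·f₀) with power integrated
  over ±0.1 Hz around each harmonic (Hann periodogram); f₀ = f_step for
  VT/AP, f_stride for ML. Note: under pure phase jitter IH *rises* with
  jitter — phase noise scales with harmonic number, so the higher
  harmonics lose power from their ±0.1 Hz windows faster than the
  fundamental. IH discriminates harmonic structure, not phase stability.
- **Harmonic ratio.** Spectral amplitudes at the first 20 stride
  harmonics (direct DFT at exact multiples); even/odd for VT and AP,
  odd/even for ML. A vanishing denominator is capped at 100 with a
  warning.
- **Local divergence rate.** Rosenstein estimate per axis: delay
  embedding (dimension 5, delay 10 samples), nearest neighbour excluding
  temporal neighbours within one stride, mean log divergence followed for
  half a stride, least-squares slope × stride time (per-stride units).
  Distances are floored at 1e-10 of the signal SD so that
  machine-epsilon separations on noiseless periodic signals do not
  produce spurious slopes. Epochs with < 100 embedded points are flagged.
- **Sample entropy.** SampEn(m = 2, r = 0.2·SD), Chebyshev distance,
  self-matches excluded, both template lengths drawn from the same N−m
  starting positions (a constant signal gives exactly 0).
- **Composite score.** Weighted sum of z-scored inputs: stride-frequency
  autocorrelation, power at step frequency, RMS acceleration, index of
  harmonicity. Cohort-specific weights and standardization constants are
  supplied through configuration; defaults are equal weights (0.25) with
  identity standardization, and both a relative (dominant power fraction)
  and an absolute step-frequency power are exposed as candidate inputs.

Epoch failures flag the row (`valid=False` with a reason) rather than
aborting the batch.

## Weekly aggregation

Per (subject, week, characteristic): the median over valid epochs, with
the cell set to missing when fewer than `min_epochs` (default 10) valid
values exist, and per-cell counts recorded. Two-week analyses use
complete cases only. The minimum-epoch threshold is a wear-time guard
with no canonical value; it is deliberately configurable.

## Variance components

For two weeks j = 1,2 and n subjects, the weekly value is modeled as
x_ij = μ + b_i + u_ij + e_ij with independent Gaussian components of
variance σ²_BS (between subjects), σ²_WS (within subject, between weeks)
and σ²_E (sampling error of the weekly median). The balanced two-way
decomposition gives MS_subject and MS_error; the method of moments yields
s²_BS = (MS_subject − MS_error)/2, truncated at zero with a flag if
negative (never silently). The week effect is tested as F = MS_week /
MS_error on (1, n−1) df — identical to the squared paired t statistic —
and between-week agreement is the Pearson r, whose model expectation is
σ²_BS/σ²_total.

With only two weekly values per subject, σ²_WS and σ²_E are not
separately identifiable: MS_error estimates their sum. When day-level
values are available the sampling variance of the weekly median is
estimated directly and subtracted: Var(median of K days) ≈ c_K × s²_day,
where s²_day is the pooled within-week day-to-day variance and c_K the
variance of the median of K standard normal draws, computed once by
Monte Carlo (10⁵ draws, fixed internal seed; the asymptotic π/(2K) is
poor at small K). This calibrated estimator is unbiased under the
Gaussian day model. A nonparametric bootstrap of the median
(`median_variance_method="bootstrap"`, 200 resamples) is provided for
sensitivity analysis but is *not* the default: at K = 7 its expectation
overshoots the true sampling variance by ≈ 31%, which would corrupt the
σ²_WS/σ²_E split. Without day-level data the package reports
`separable_error=False`, σ²_WS = 0 and σ²_E = MS_error; the sample-size
formula is unaffected since it uses only the total and between-subject
components.

## Cohort simulation

`cohort_sim` draws from the same additive model. In day-level mode
(days_per_week K > 1) day values get noise variance σ²_E/c_K so the
weekly median's sampling variance equals σ²_E exactly, mirroring how
weekly medians acquire error variance from finitely many monitored days.
An optional additive week-2 shift supports power-validation experiments.
Eighteen published parameter sets (18 fall-associated characteristics:
mean, σ²_BS, σ²_WS, σ²_E, plus the reported week-effect p and
between-week r) ship as presets; the composite-score preset implies a
between-week correlation of 0.547/0.685 ≈ 0.798.

## Sample size

With Δ = d·√s²_total the formula reduces to the scale-free
f(n) = 2·(1 − r·ρ)·(t_{n−1,1−β} + t_{n−1,1−α/2})²/d², ρ = σ²_BS/σ²_total.
Standardizing by the total SD is the standard Cohen's-d convention and
the only choice that makes n depend on a characteristic solely through ρ.
Because n appears in the t quantiles, the reported value is the smallest
integer n ≥ 2 with n ≥ f(n) (f is decreasing in n, so this is
well-defined; naive fixed-point iteration can oscillate at small n). The
search starts at the normal-quantile closed form and scans outward;
α = 0.05 two-sided and power 0.8 are the defaults. Useful structure:
n is linear in r (a straight-line fit across a grid row recovers ρ);
n scales as 1/d² asymptotically, but at n ≈ 20 (large effects) the
t-correction inflates n by ~10%, so n(0.3)/n(0.8) sits around 6.3–6.5
rather than the asymptotic (0.8/0.3)² ≈ 7.11.

## Numerical and testing notes

- All simulators are deterministic given an integer seed
  (`numpy.random.default_rng`); the calibration constant c_K uses a fixed
  internal seed so it is a constant of K, independent of cohort draws.
- SampEn and the local divergence rate are verified against independent
  O(N²) loop implementations to 1e-6; the ANOVA against hand arithmetic
  to 1e-9; the sample-size search against an exhaustive integer scan.
- Acceptance-style checks simulate 5000-subject cohorts (≈ 1 s each);
  test-suite signal fixtures use 10–30 s episodes.
- The analysis assumes near-Gaussian weekly values (the variance
  decomposition is method-of-moments; the F test is exact under
  normality). Heavy-tailed day distributions would bias the calibrated
  median-variance factor; the bootstrap option exists to probe that.
- Realignment resolves yaw only up to 180° (sign of ML/AP); per-axis
  characteristics used here are insensitive to the joint sign flip.

## Known limitations

- The synthetic signal generator is a harmonic-plus-phase-noise model,
  not a biomechanical simulation; effect sizes measured on it do not
  transfer to real populations.
- Composite weights are configuration inputs; no canonical weight set is
  bundled, and results with the default equal weights are not comparable
  across cohorts without shared standardization constants.
- With two measurement weeks the within-subject/error split relies
  entirely on day-level data and the Gaussian day model.
- The sample-size formula addresses a single-group paired comparison;
  two-arm parallel designs, dropout inflation and multiplicity across
  characteristics are out of scope.
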