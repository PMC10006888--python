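# Methods

This note documents the models, algorithms and design choices behind
`gaitfreq`, in the order the pipeline runs them.

## Synthetic cohort generator

**What it emulates.** Each participant contributes one tri-axial thigh
acceleration recording (craniocaudal / anteroposterior / mediolateral) of a
steady walking bout, sampled at 12.5 Hz, plus demographics, five KOOS
subscale scores (0–100, higher = better) and — for patients — a
Kellgren–Lawrence (KL) grade 1–4 and an affected side. Signals are built
per axis as

    x(t) = offset + Σ_{i=1..6} √P_i · cos(i·(ω t + δ_c) + φ_i) + ε(t)

with subject fundamental ω = 2π/T, per-cycle phase jitter δ_c ~ N(0,
0.05 rad) (stride-timing variability, the disturbance that cycle averaging
is designed to suppress), white noise ε ~ N(0, 0.05 m/s²), and a constant
per-axis offset (≈9.4 / 1.5 / 0.8 m/s² CC/AP/ML) standing in for the
quasi-static gravity projection of a thigh-worn sensor. Units are m/s²
throughout; the downstream model is scale-equivariant after
standardization, so the absolute scale is a convention.

**Default parameters.** 27 patients / 18 controls; female fractions 15/27
and 11/18; age 67.2 ± 9.4 vs 60.8 ± 5.4 years; BMI 27.7 ± 3.8 vs
23.7 ± 3.0 kg/m² (truncated at the 35 kg/m² exclusion threshold); stride
period 1.10 ± 0.11 s (patients) vs 1.02 ± 0.04 s (controls), clipped to
[0.94, 1.45] s. Control harmonic-power targets are group-typical means per
axis; patient targets equal the control targets scaled by per-harmonic
ratios. The group effect is deliberately *concentrated* in four harmonics —
P(f₂)_CC (ratio 0.64), P(f₅)_CC (0.50), P(f₆)_CC (0.25) and P(f₅)_AP
(0.45) — with a mild 0.92 elsewhere and exactly 1.0 for P(f₁)_ML and
P(f₄)_ML, so that the feature-selection experiments have a well-defined
ground truth. Per-subject heterogeneity is a mean-one lognormal multiplier
per power with per-harmonic log-SDs (0.27–1.05) chosen so the implied
standardized group effects (≈0.8–1.9 on the discriminative harmonics) and
hence the achievable classification accuracy (~0.9) match a realistic
unilateral-knee-OA cohort of this size. Mean-one multipliers make the
expected extracted power equal the planted target exactly, which keeps
coverage simulations well-posed.

A severity index s ~ U(0,1) per patient links the pieces: it maps to KL
grades with proportions ≈26/30/33/11%, lowers KOOS scores linearly
(slope 40 points, residual SD 8, clipped to [0,100]; controls sit near the
ceiling), and scales the planted power ratios via an exponent 0.4 + 1.2·s —
more severe patients lose more harmonic power, giving the monotone
G0→G1→G2 trends the severity analyses look for.

Two auxiliary constructions: `matched_config()` equalizes demographics and
stride periods across groups (signal lives only in the powers);
`recovery_config()` additionally nulls every power effect except the four
headline harmonics, so any other selected variable is spurious by design.

**What it does not emulate.** No biomechanical forward simulation: no joint
kinematics, no double-support asymmetry, no turning or stopping, no sensor
drift or orientation error, no aliasing from above-band content (signals
are synthesized band-limited, except that the fastest walkers' sixth
harmonic may exceed the 6.25 Hz Nyquist limit, as it would in reality).
Passing tests therefore demonstrate correctness of the *pipeline* under
the stated signal model, not fidelity to any particular clinical dataset.

## Signal processing

**Stride period.** The normalized autocorrelation of the mean-subtracted
CC axis is searched in [0.4, 2.0] s (plausible human stride periods). A
peak below 0.2 raises an "aperiodic signal" error (white noise at this
length fluctuates near ±0.05). The discrete peak is refined by parabolic
interpolation, guarded against octave errors (a sharp multi-harmonic peak
falling between lag samples can score below its own double; sub-multiples
of the peak lag are preferred when their interpolated autocorrelation
reaches 80% of the peak), and polished by a phase-drift iteration: the
strongest harmonic is demodulated in two Hann-tapered half-windows and the
phase difference converts directly into a frequency correction. The Hann
tapers suppress the negative-frequency interference that would otherwise
bias the estimate at the 10⁻⁴ level; after refinement the period of a
noiseless periodic signal is exact to ~10⁻⁷ s, which the 10⁻⁶-level power
recovery guarantees require.

**Interpolation.** `fourier_interpolate` evaluates the full-window
trigonometric (DFT) interpolant: exact at the sample points, band-limited
in between, correct up to the Nyquist bin. For signals whose period is
incommensurate with the window length the implied periodic extension has a
wrap discontinuity, which leaks O(10⁻³) into interior values. The cycle
extractor therefore removes a least-squares harmonic series at the known
stride period (up to the highest harmonic under Nyquist, at most 8) before
interpolating and adds it back analytically at the query times: the
periodic component is resampled exactly — including harmonics near the
band edge — while cycle-to-cycle variability (jitter, noise) survives in
the interpolated residual and is genuinely averaged.

**Cycle averaging.** Ten contiguous cycles centred on the trial midpoint
(the recording must span at least n_cycles + 4 strides; "middle of the
bout" is defined as symmetric about the midpoint sample). Each cycle is
resampled onto m = 64 equally spaced points over one period and the
average is the pointwise mean. Cycle start phase is arbitrary — no
heel-strike detection — which is justified because the harmonic powers are
invariant to circular shifts. Per-axis means (gravity + DC) are subtracted
before all spectral computation; the feature set starts at the first
harmonic.

**Harmonic powers.** From the averaged cycle of M points:
a_i = (2/M) Σ_k x_k cos(2πik/M), b_i likewise with sin, and
P(f_i) = a_i² + b_i² for i = 1…6 ("sum of the squares of the i-th
coefficient pair", no ½ factor — any constant convention cancels after
standardization). M ≥ 14 is required for six harmonics. With 12.5 Hz
sampling and ~1 s strides the sixth harmonic sits at the edge of the
usable bandwidth; that is a property of the sensor class, not of the
implementation.

## Feature table

22 explanatory variables — age, sex, BMI, ω, and 18 powers — with knee-OA
status as the outcome (1 = patient). Continuous variables are standardized
to zero mean / unit variance; sex is a 0/1 dummy (female = 1) and is
penalized like any other column but never rescaled. The table keeps raw
values plus the scaling parameters: all cross-validation and repeated-split
code re-standardizes on the training portion only, because standardizing
once on the full sample would leak location/scale information into held-out
folds.

## Penalized logistic regression

The objective is the 1/n-scaled negative Bernoulli log-likelihood plus
λ‖β‖₁ (intercept unpenalized). This scaling follows the convention of the
widely used R implementation, which makes reported λ magnitudes comparable
across software. The solver is IRLS with an inner cyclic coordinate
descent: quadratic approximation at the current fit (probabilities clipped
to [10⁻⁹, 1−10⁻⁹], weights floored at 10⁻⁹), soft-threshold updates,
alternating full sweeps with active-set-only sweeps, convergence when the
largest coefficient change falls below 10⁻⁷. The kernel is numba-compiled.
The path runs over 100 log-spaced λ from 10² down to 10⁻¹², warm-started;
λ ≥ λ_max = max_j |x_jᵀ(y − ȳ)|/n short-circuits to the exact null model.
Under complete separation at tiny λ the coefficients diverge slowly; the
iteration caps (30 IRLS steps) stop the fit and mark it non-converged
rather than looping — KKT certificates are asserted only for converged
points.

**Penalty selection.** Stratified 10-fold CV (stratification matters at
n = 45; a failed stratification redraws folds with a shifted seed). Per
fold: re-standardize on the training folds, fit the path, record held-out
mean binomial deviance per λ. λ_min minimizes the across-fold mean
(largest λ on ties); SE is the across-fold SD divided by √k; λ_1se is the
largest grid λ whose mean deviance is within one SE of the minimum — on a
discrete grid this is the first qualifying point from the top.

**Selective inference.** At fixed λ = λ_1se the logistic fit is mapped to
its Gaussian one-step approximation: with M = [1, X_E] the active-set
design, W the IRLS weights at the solution and Σ = (MᵀWM)⁻¹, the debiased
estimator b̄ = β̂_M + Σ Mᵀ(y − p̂) is treated as N(β, Σ) (dispersion fixed
at 1). The selection event {sign(β̂_E) = s} linearizes to the polyhedron
−s_r b̄_{r+1} ≤ −nλ s_r (Σ s̃)_{r+1}, and the polyhedral lemma gives each
active coordinate a truncated-Gaussian pivot; CIs invert the pivot by
bisection (the pivot is monotone in the mean), with a wide grid scan as
fallback and an unconditional interval — flagged — if even that is
degenerate. Tail arithmetic runs in log space so deep truncations do not
underflow. These intervals are valid conditional on the selection, which
is why they are much wider than naive Wald intervals at n = 45.

## Classification evaluation

Ten repeated stratified 75/25 splits. Per split: standardize on the
training part, select λ_1se by internal 10-fold CV *inside the training
set* (re-selection avoids selection leakage; a fixed-λ mode exists for
comparison), fit, predict the held-out quarter at threshold 0.5, record
accuracy and Cohen's κ = (p_o − p_e)/(1 − p_e) from the held-out confusion
matrix (κ per split, then averaged — not pooled; κ defined as 1 when both
p_o = p_e = 1). Summary: mean ± 1.96·SD/√(n_repeats). The confounder-only
ablation (age, BMI, ω — sex excluded) runs on identical splits.

## Severity statistics

KOOS terciles use the 33rd/67th percentiles (linear interpolation) of the
pooled scores of all participants; boundary values join the milder
(higher-score) group; controls' ceiling scores land them in G0 naturally.
The KL grouping maps controls → G0, KL 1–2 → G1, KL 3–4 → G2. Wilcoxon
rank-sum tests use midranks, exact enumeration when min(n) ≤ 8 without
ties, and the tie- and continuity-corrected normal approximation
otherwise. Difference-of-means CIs are Welch t intervals (reported
alongside the nonparametric p-values, mirroring common practice even
though the data are non-normal). Raw p-values are reported without
multiplicity correction; a Holm-adjusted column is emitted next to them,
clearly labelled as an extension. Cadence is derived as 120/T steps per
minute (two steps per stride). The sex-by-group comparison is a
continuity-corrected chi-square; Shapiro–Wilk screens continuous variables
for normality.

## Pipeline

One global seed is expanded through `numpy.random.SeedSequence` into
independent per-stage streams (cohort, CV, evaluation, trial choice), so
adding a stage never perturbs earlier draws and reruns are byte-identical.
When a participant has several recorded walks on disk, one is chosen by a
seeded draw. Every artifact embeds the seed and a config hash; the
manifest lists SHA-256 checksums and per-stage timings, and a failed stage
leaves a manifest marking which stage failed.

## Problem sizes and runtime

The shipped experiments use the study-scale cohort (45 participants,
30 s × 12.5 Hz trials). Representative timings on one CPU core: feature
extraction for 45 trials ≈ 0.5 s; one 100-λ path ≈ 0.05 s warm; 10-fold CV
≈ 2 s; the full repeated-split evaluation of both models ≈ 20 s; the whole
end-to-end run well under two minutes. Simulation-based checks
(coverage, null-model selection, recovery) use 20–200 seeds at n = 45–100.

## Known limitations

- The 1-SE rule at n = 45 is noisy: across seeds λ_1se ranges roughly
  0.03–0.2 and the active set 0–10 variables even when exactly four
  features carry signal. This matches the reference R implementation on
  identical data and is a property of cross-validation at this sample
  size, not of the solver.
- Selective CIs use the one-step Gaussian approximation with dispersion 1;
  for small n and strong separation the approximation is rough, and the
  truncation interval can degenerate (flagged in the output).
- The stride-period estimator assumes a dominant common periodicity; it
  will lock onto a sub-multiple if a single higher harmonic carries
  essentially all the power (a pure i-th harmonic has no information about
  the fundamental).
- Near the Nyquist limit (sixth harmonic of fast walkers) extracted powers
  are attenuated by jitter averaging and carry interpolation error at the
  10⁻³ level — consistent between groups, hence immaterial after
  standardization, but not suitable for absolute spectral calibration.
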