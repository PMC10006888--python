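# gaitfreq

Frequency-domain gait analysis of low-sampling-rate thigh accelerometry for
knee-osteoarthritis (OA) classification.

Simple wearable accelerometers designed for weeks-long recording sample
slowly (here 12.5 Hz) and carry no gyroscope, so conventional gait analysis
— event detection, joint kinematics — is out of reach. What such a sensor
does capture well is the *harmonic structure* of the quasi-periodic
acceleration signal over a stride. `gaitfreq` implements a complete,
testable pipeline built on that idea, for biostatisticians and movement
scientists working with remote-monitoring data:

1. **Signal processing** — band-limited (trigonometric) interpolation of the
   tri-axial signal (craniocaudal CC, anteroposterior AP, mediolateral ML),
   autocorrelation-based stride-period estimation, averaging of ten gait
   cycles from the middle of the walking bout, and Fourier analysis of the
   averaged cycle.
2. **Features** — the fundamental angular stride frequency ω = 2π/T and the
   harmonic powers P(f_i) = a_i² + b_i², i = 1…6, per axis, where (a_i, b_i)
   is the i-th Fourier coefficient pair of the averaged cycle: 19 gait
   features, plus age, sex and BMI (22 explanatory variables).
3. **Classification & selection** — logistic LASSO fitted by penalized
   maximum likelihood over a descending penalty grid λ ∈ [10⁻¹², 10²],

       min  (1/n) Σᵢ log(1 + exp(−ỹᵢ(β₀ + xᵢᵀβ))) + λ‖β‖₁ ,   ỹ ∈ {−1, +1},

   solved by IRLS + cyclic coordinate descent with warm starts; λ chosen by
   stratified 10-fold cross-validation of held-out binomial deviance, with
   both λ_min (deviance minimizer) and λ_1se (the largest λ within one
   standard error of the minimum).
4. **Post-selection inference** — truncated-Gaussian 95% CIs and p-values
   for the active coefficients at fixed λ = λ_1se, via the polyhedral lemma
   applied to the one-step Gaussian approximation of the logistic fit.
5. **Evaluation & severity** — accuracy and Cohen's κ over repeated
   stratified 75/25 splits (penalty re-selected inside each training set),
   a confounder-only ablation (age, BMI, ω), and comparisons of the selected
   features across disease-severity groups (KOOS-subscale terciles and
   Kellgren–Lawrence grade groups G0/G1/G2) with Wilcoxon rank-sum tests
   and Welch difference-of-means CIs.

Because raw clinical recordings of this kind are typically not public, the
package ships a first-class **synthetic cohort generator**: seeded,
study-shaped cohorts (27 patients with unilateral knee OA / 18 controls by
default) whose per-harmonic powers, demographics, KOOS scores and KL grades
follow group-typical distributions, with planted effects concentrated in
P(f₂)_CC, P(f₅)_CC, P(f₆)_CC and P(f₅)_AP. Every downstream stage is tested
against it.

## Worked example

```python
import gaitfreq as gf
from gaitfreq.signal import cohort_feature_frame

cfg = gf.default_config(seed=7)                 # 27 patients, 18 controls
participants, trials = gf.generate_cohort(cfg)
features = cohort_feature_frame(trials)          # omega + 18 harmonic powers
table = gf.build_feature_table(participants, features)

cv = gf.cv_select_lambda(table, k=10, seed=7)
print(f"lambda_min = {cv.lambda_min:.3f}, lambda_1se = {cv.lambda_1se:.3f}")

fit = gf.fit_at(table, cv.lambda_1se)
ci = gf.selective_inference(fit, table)
print(ci.table[["coefficient", "lower", "upper", "p_value"]].round(3))

full, conf = gf.compare_models(table, seed=7)
print(f"full model:       accuracy {full.mean_accuracy:.2f}, "
      f"kappa {full.mean_kappa:.2f}")
print(f"confounders only: accuracy {conf.mean_accuracy:.2f}, "
      f"kappa {conf.mean_kappa:.2f}")
```

Output (seed 7):

```
lambda_min = 0.040, lambda_1se = 0.056
         coefficient  lower  upper  p_value
feature
age            0.338 -1.632  1.895    0.505
bmi            0.484 -0.765  2.050    0.250
omega         -0.386 -1.793  1.662    0.532
P_f2_CC       -0.808 -2.405  0.063    0.060
P_f5_CC       -0.193 -1.207  3.744    0.794
P_f6_CC       -0.446 -2.395  2.577    0.681
P_f5_AP       -0.640 -2.235  1.799    0.538
full model:       accuracy 0.83, kappa 0.64
confounders only: accuracy 0.68, kappa 0.29
```

Reading this: the 1-SE penalty keeps seven variables; the four retained gait
harmonics all carry negative signs (patients have *less* power at those
stride harmonics than controls), while the selective CIs — which account
for the fact that the LASSO chose these variables — are wide at n = 45.
The full model classifies held-out participants markedly better than age,
BMI and stride frequency alone, i.e. the discriminative information lives
in the harmonic powers, not the demographics.

## Command line

```bash
gaitfreq run --seed 17 --out results/        # simulate + full analysis
gaitfreq simulate --seed 1 --out cohort/     # write trial CSVs + metadata
gaitfreq extract-features --trials cohort/trials --out feats/
gaitfreq fit --features feats/features.csv --metadata cohort/metadata.csv
gaitfreq evaluate --features ... --metadata ...
gaitfreq severity --features ... --metadata ...
```

`run` writes seven artifacts (features, CV curve, coefficient path,
coefficient report, two evaluation JSONs, severity comparisons) plus a
`MANIFEST.json` with SHA-256 checksums, the seed and a config hash; reruns
with the same seed are byte-identical. `--plots` adds CV-curve and
coefficient-profile figures.

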