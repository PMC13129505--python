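# Methods

`benage` implements a complete resting-state fNIRS brain-entropy → brain-age
analysis: raw dual-wavelength optical intensities are converted to
hemoglobin concentration series, their complexity is summarized by
permutation entropy (static and sliding-window dynamic), a linear support
vector regression predicts age from those entropy features in healthy
controls, and the brain-age gap (BAG) and ROC machinery quantify how a
patient group departs from the control aging trajectory. Because the
clinical recordings the analysis was designed around are not public, the
package ships a synthetic cohort generator that plants the statistical
structure the analysis assumes, so every stage is testable end to end.

## Preprocessing

**Pipeline order** (fixed, logged per recording):
despike → low-pass → modified Beer–Lambert inversion → CV-based channel QC,
with QC always computed on the *raw* intensities.

- **Channel quality control.** Coefficient of variation CV = σ/μ of the raw
  intensity series per channel and wavelength (population σ). A channel is
  excluded iff CV > 7.5% at either wavelength; the inequality is strict, so
  a channel exactly at threshold is retained. `cv_table`/`apply_qc` compute
  the CV through the same `compute_cv` code path so the boundary behavior
  is bit-consistent.
- **Despiking.** The source analysis only states that spike artifacts were
  removed; we chose a deterministic, testable rule: samples with robust
  z-score |x − median| / (1.4826·MAD) > 5 in runs of ≤ 3 samples are
  replaced by linear interpolation across the flanking clean samples.
  Longer runs (and runs touching the series boundary) are left untouched
  and logged; a zero MAD falls back to an exact-deviation rule. Spline or
  wavelet motion correction is out of scope.
- **Filtering.** Zero-phase (forward–backward) Butterworth low-pass,
  order 3, cutoff 0.2 Hz. The family and order are unstated in the source
  analysis; this is a common fNIRS default with unit DC gain and > 12 dB
  attenuation at twice the cutoff.
- **MBLL.** ΔOD(λ,t) = −log₁₀(I/I₀) with I₀ defaulting to the per-channel
  temporal mean (zero-mean ΔOD); concentrations solve
  E·[ΔHbO; ΔHbR] = ΔOD/(d·DPF) with source–detector separation d = 3 cm and
  DPF = 6 at both wavelengths (values unpublished for the acquisition
  device; editable). Extinction coefficients at 730/850 nm come from the
  standard compiled hemoglobin spectra (HbO₂ 390 / Hb 1102.2 and HbO₂
  1058 / Hb 691.32 cm⁻¹ M⁻¹); the 2×2 matrix has condition number ≈ 3, so
  the inversion is numerically benign. The generator implements the exact
  forward model, and the round trip is verified to < 1e−9 μM.
- An entry point for already-converted concentration series
  (`from_concentrations`) skips the inversion, since acquisition software
  commonly exports HbO/HbR directly.

## Permutation entropy

For a series x with embedding dimension d = 3 and lag τ = 1, each vector
(x_t, x_{t+τ}, …, x_{t+(d−1)τ}) maps to the permutation that sorts it; PE is
the Shannon entropy of the pattern frequencies, normalized by ln(d!) to
[0, 1]. Ties are broken by temporal order (stable sort: the earlier sample
ranks lower), which makes constant segments map deterministically to the
ascending pattern; a seeded tiny-jitter alternative is provided because
constant runs are pattern-degenerate and a different convention changes the
value on quantized data. The implementation is vectorized over channels and
windows and is tested for exact pattern-count agreement with a naive
enumeration oracle, affine invariance, and the [0, 1] bounds.

- **Static BEN**: PE of the full series per channel per signal
  (HbO/HbR/HbT) — 78 measures at 26 retained channels.
- **Dynamic BEN**: PE in sliding windows of 200 samples (~30 s at
  2000 samples / 5 min) advancing by 100 samples (50% overlap), summarized
  by the mean (an SD summary is available). Window length, step and summary
  are unstated in the source analysis; these defaults are exposed in
  configuration and results are sensitive to them — a documented caveat.
- **Feature sets**: HbO/HbR/HbT × static/dynamic, their unions Static_all
  (78), Dynamic_all (78) and ALL (156). Channels failing QC for *any*
  subject are dropped cohort-wide (complete-case columns), the simplest
  defensible rule for a downstream SVR that cannot handle missing cells.

## Brain-age model

Training is confined to the control group under leave-one-out
cross-validation. Within each training fold:

1. **Screening**: partial Pearson correlation of each feature with age,
   controlling sex and education by least-squares residualization; keep
   |r| > 0.1. The threshold is deliberately permissive (about half of pure
   noise features survive it at n ≈ 49; verified by simulation) — the SVR
   does the real shrinkage. The source analysis lists age itself among the
   covariates of this age correlation, which is internally inconsistent;
   we control sex and education only. Screening is recomputed inside every
   fold (leakage-safe); a one-shot global screen is available as a
   replication mode.
2. **Standardization**: features are z-scored with training-fold statistics
   (SVR is scale-sensitive; not mentioned in the source analysis; off
   switch provided).
3. **Model selection**: linear SVR (ε = 0.1), C over {1, 10, 100, 1000} by
   inner 5-fold CV minimizing pooled RMSE; ties broken by higher inner
   correlation, then smaller C. The source analysis gives no inner-CV
   structure; nested outer-LOOCV / inner-5-fold is the standard
   leakage-safe reading.

An empty post-screen fold falls back to all features with a logged warning.
BAG = predicted − biological age, with no regression-to-the-mean
correction — the positive control-group BAG this leaves is consistent with
the uncorrected convention. For the patient group the default is a single
final model refit on all controls with the modal fold-selected C (ties to
the smaller C); an ensemble mode instead averages the per-fold models'
predictions (both are supported because the source description admits both
readings; they agree closely in practice).

## Group statistics and discrimination

- Pooled-variance two-sample t (not Welch), because the pooled form
  reproduces the published group-comparison table from its printed
  (mean, SD, n) summaries to 2 dp. A summary-statistic entry point
  (`t_from_summary`) makes those worked examples first-class.
- Benjamini–Hochberg FDR (q = 0.05) via statsmodels; Pearson age
  correlations with their own FDR column.
- Pearson chi-square without continuity correction (again the form that
  matches the printed value).
- ROC by Mann–Whitney pair counting (ties = ½), with the threshold-swept
  curve whose trapezoid area equals the rank AUC exactly; scores are
  oriented so AUC ≥ 0.5, with the orientation recorded.
- The **combination discriminant** is an unpenalized (maximum-likelihood)
  logistic regression on the z-scored selected features. With dozens of
  features and ~84 subjects this separates the groups perfectly in-sample —
  exactly the regime in which combination AUCs of 1.00 get reported — so
  both the in-sample AUC (replication of that convention) and a stratified
  5-fold CV AUC (the honest estimate; typically ≈ 0.55–0.65 here) are
  returned, clearly labeled.

## Synthetic cohorts

Each subject's channels share a latent mixing parameter
m = clip(m₀ + β_age·z(age) + β_group·1[MDD] + ε_subj, 0, 0.95) and each
channel's latent series is s(t) = (1−m)·noise + m·oscillation, with
band-limited Gaussian noise (low-passed at 0.8×Nyquist) and a deterministic
0.05 Hz oscillation of random phase. HbO = 0.5 μM·s; HbR = −0.4·HbO plus
small independent noise (typical anticorrelated hemodynamics; the factor is
a free default); HbT = HbO + HbR. Raw intensities come from the exact
forward Beer–Lambert model, so preprocessing is round-trip testable.
Optional artifacts: 1–3-sample spikes of ≥ 5 SD at a configurable rate, and
variance-inflated channels whose CV exceeds the QC threshold.

PE responds monotonically to m *after* the pipeline's 0.2 Hz low-pass
(≈ 0.51 at m = 0.1 down to ≈ 0.44 at m = 0.9; verified over repeated
realizations) — on the broadband latent series the response is nearly flat,
so all monotonicity and recovery claims are about the filtered
concentrations the analysis actually consumes.

**Defaults as study conditions.** 49 controls / 35 patients, 26 channels,
2000 samples at fs = 2000/300 Hz, ages uniform 18–65, m₀ = 0.5,
subject noise SD 0.05, β_age = −0.3 (older ⇒ lower m ⇒ higher PE) and
β_group = −0.3. The group offset was calibrated once to the discrimination
geometry reported for the reference clinical cohort — single-channel AUC
≈ 0.73 implies a standardized group effect d ≈ 0.9–1.0, and with the
age-driven within-group mixing SD of ≈ 0.30 that fixes |β_group| ≈ 0.3.
The signs are a free, documented choice: the analysis direction is
recovered for any *aligned* pair (β_group shifting patients toward the
entropy signature of older age); both signs are exposed because the true
direction in the reference data is only partially reported. The generator
does not model cardiac/respiratory oscillations, Mayer waves or
optode-coupling drift, so passing tests demonstrate pipeline correctness
and sensitivity under the planted model — not performance on real
recordings.

## Validity experiments and problem sizes

- **Planted-effect recovery** (`benage.experiments.parameter_recovery`):
  five cohorts at the reference size run the full pipeline on static BEN
  features (they carry the planted signal identically to the dynamic
  summaries at a fraction of the compute). Observed: LOOCV r ≈ 0.89–0.94,
  BAG(MDD) − BAG(HC) ≈ 7–11 years with pooled-t p < 1e−7, significant-
  channel combination in-sample AUC = 1.00 (CV AUC ≈ 0.55–0.6).
- **Null false-discovery** (`null_discovery_rate`): 200 cohorts with
  β_group = 0; the 78-feature pooled-t + BH pipeline should flag any
  discovery in ≤ ~5% of cohorts (BH controls the family-wise rate under
  the complete null; features are positively correlated through the shared
  mixing parameter, which only makes the test conservative).

## Numerical choices and degenerate inputs

- Constant features: partial r defined as 0 (excluded from screening), with
  an absolute-residual guard because constants residualize to ~1e−16 dust.
- Zero pooled SD in the t-test: t = 0 for equal means, signed infinity
  otherwise (p = 0, flagged by the caller's context).
- Zero-MAD despiking falls back to exact-deviation flagging; fully constant
  series pass through.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration + seed reproduces
  every CSV byte for byte (asserted in tests).

## Known limitations

- The generator is a complexity knob, not a hemodynamics simulator; effect
  sizes are calibrated to reported discrimination geometry, not fitted to
  data.
- Dynamic-BEN window parameters are conventions, not identified values.
- The clinical headline numbers (control LOOCV r = −0.62 on real data,
  patient BAG ≈ 8 years, specific channel AUCs) require the original
  recordings and are treated as context, never as expectations of the
  synthetic pipeline — note the *sign* of the real-data r differs from the
  synthetic recovery runs, where predicted and biological age correlate
  positively because the planted gradient is strong.
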