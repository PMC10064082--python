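# mrgap

Two-sample Mendelian randomization (MR) estimators and an observational
glycation-gap pipeline, for studying how hyperinsulinemia relates to
erythrocytosis and to the non-glycemic component of HbA1c — plus seeded
synthetic-data generators so every stage runs and is testable without
access to consortium GWAS data or hospital records.

**Who it is for.** Epidemiologists and biostatisticians who have GWAS
summary statistics (one row per SNP: alleles, EAF, β, SE, p, n) for an
exposure such as fasting insulin and outcomes such as hemoglobin or
HbA1c, and/or a patient-level cohort with fasting glucose,
triglycerides, HbA1c and hemoglobin, and who want the full
harmonize → estimate → sensitivity-check → validate workflow as a
library rather than a point-and-click tool.

## What it computes

**Univariable MR** (`mrgap.mr`). With per-SNP exposure effects
β̂_Xj ± σ_Xj and outcome effects β̂_Yj ± σ_Yj:

- IVW: θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂²_Xj, w_j = 1/σ²_Yj, with
  fixed-effect SE (Σ w_j β̂²_Xj)^(−1/2) optionally inflated by
  √max(1, Q/df) (multiplicative random effects, the default);
- MR-Egger: the same weighted regression with a free intercept, which
  estimates average directional pleiotropy;
- weighted median and simple/weighted mode of the Wald ratios
  θ̂_j = β̂_Yj/β̂_Xj, with parametric-bootstrap SEs;
- Cochran's Q, I² = max(0, (Q−df)/Q)·100, mean instrument
  F = mean(β̂_Xj/σ_Xj)², leave-one-out, and scatter/funnel table exports.

**Multivariable MR** (`mrgap.mvmr`). Direct effects of K exposures by
zero-intercept weighted regression of β̂_Yj on the K exposure-effect
columns, with Sanderson–Windmeijer conditional F per exposure and a
collinearity guard.

**Harmonization** (`mrgap.summary_stats`). File reading with a
configurable column map, strict p < 5·10⁻⁸ instrument selection,
LD-proxy substitution from a user-supplied (SNP, proxy, r²) table, and
allele alignment that resolves label swaps and strand flips and handles
palindromic SNPs by allele-frequency inference (ambiguity band
0.42–0.58) or outright dropping.

**Glycation gap** (`mrgap.glycation`). Cohort filters (age 18–65,
FG < 7 mmol/L, HbA1c < 6.5%, sex-specific hemoglobin range), glycemic
classification (normoglycemia: HbA1c < 6% and FG < 6 mmol/L; pre-T2D:
the complement), the triglyceride-glucose index
TGI = ln(TG[mg/dL]·FG[mg/dL]/2), predicted HbA1c from fasting glucose
(default calibration 4.163 + 0.172·FG), the glycation gap
(measured − predicted HbA1c), stratified OLS of gap and hemoglobin on
TGI, residual diagnostics, and 0.632-bootstrap optimism validation.

**Synthetic data** (`mrgap.simulate`). Seeded generators for two-sample
GWAS instruments (configurable pleiotropy models, invalid-SNP fractions,
instrument strength, realistic allele bookkeeping) and for patient
cohorts whose marginals and regression structure are calibrated to the
published stratum summaries. See `docs/methods.md` for the models and
the calibration.

## Worked example

`examples/glycation_gap.py` simulates a 7,600-person cohort, filters,
classifies, and runs the stratified regressions:

```
gap ~ TGI by stratum (generator truth: -0.087 pre-T2D, +0.023 healthy):
      stratum    n    beta     se  intercept   pval     r2  r2_adj outcome
       preT2D  907 -0.0848 0.0094     1.7847 0.0000 0.0820  0.0810     gap
normoglycemia 5484  0.0125 0.0081     0.2092 0.1260 0.0004  0.0002     gap
...
0.632 bootstrap (pre-T2D gap ~ TGI): R2 apparent = 0.0820,
corrected = 0.0737, optimism = 0.0083 (not overfit)
```

The pre-T2D slope of −0.085 ± 0.009 recovers the planted −0.087:
as insulin resistance (TGI) rises, measured HbA1c falls further below
what fasting glucose predicts — the non-glycemic, erythrocytosis-
consistent signature.  The optimism of 0.008 (≪ 0.1) says the
single-predictor model is not overfit.

`examples/univariable_mr.py` runs the five-estimator table on a
simulated 49-SNP instrument with true effect 0.5:

```
                   method  n_snp   beta     se  pval        Q  Q_df      I2
                 MR Egger     47 0.3139 0.0696   0.0  93.6832  45.0 51.9658
          Weighted median     47 0.4967 0.0190   0.0      NaN   NaN     NaN
Inverse variance weighted     47 0.5028 0.0150   0.0 109.6987  46.0 58.0670
              Simple mode     47 0.5092 0.0429   0.0      NaN   NaN     NaN
            Weighted mode     47 0.4776 0.0389   0.0      NaN   NaN     NaN
```

Two of the 49 SNPs are palindromic with ambiguous frequencies and are
dropped in harmonization; IVW, median and modes sit on the truth, while
MR-Egger visibly under-shoots at this realistic instrument strength —
the known weak-instrument dilution (see `docs/methods.md`).
`examples/multivariable_mr.py` shows direct-effect estimation for two
correlated exposures.

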