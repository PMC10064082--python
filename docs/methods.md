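# Methods

This note records the statistical models `mrgap` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
choices a maintainer would want written down.

## Two-sample summary-data MR

For SNP *j* the inputs are the estimated per-allele effect on the
exposure, β̂_Xj ± σ_Xj, and on the outcome, β̂_Yj ± σ_Yj, taken from two
non-overlapping GWAS.  All estimators assume the instrument SNPs are (i)
robustly associated with the exposure, (ii) free of horizontal
pleiotropy (or deviate from it in the specific way each sensitivity
estimator tolerates), and (iii) unconfounded.  Instruments are treated
as independent (post-LD-pruning panels).

* **Wald ratio** — θ̂_j = β̂_Yj/β̂_Xj with first-order delta-method SE
  σ_Yj/|β̂_Xj|.  The exposure-side sampling error is ignored, the usual
  approximation for genome-wide-significant SNPs; its breakdown at
  modest instrument strength is what produces the weak-instrument
  dilution discussed below.
* **IVW** — zero-intercept weighted regression of β̂_Yj on β̂_Xj with
  weights w_j = 1/σ²_Yj, identical to the inverse-variance meta-analysis
  of Wald ratios.  Default is the multiplicative random-effects model:
  the fixed-effect SE is inflated by √max(1, Q/df), so heterogeneity can
  widen but never narrow the interval.  The `fixed` model is a flag away.
* **MR-Egger** — the same regression with a free intercept, fitted after
  orienting every SNP so β̂_Xj > 0 (the estimator is not invariant to
  allele recoding; positive-exposure orientation is the convention).
  The intercept estimates average directional pleiotropy; the slope is
  unbiased under InSIDE *and* NOME.  SEs carry the same √max(1, Q/(J−2))
  inflation; p-values use t with J−2 df (the intercept consumes a df),
  while all other estimators use normal p-values.
* **Weighted median** — Wald ratios sorted ascending with normalized
  inverse-variance weights w_j (from the delta-method ratio SEs); the
  estimate interpolates the sorted ratios at standardized cumulative
  weight S_j − w_j/2 = 1/2.  Consistent while valid SNPs hold > 50% of
  the weight.  SE by parametric bootstrap: β̂_Xj, β̂_Yj are resampled from
  N(β̂, σ²), the median recomputed, and the SD over replicates taken
  (default 1000 replicates, seeded).
* **Simple / weighted mode** — normal-kernel density of the Wald ratios,
  bandwidth φ·0.9·min(sd, IQR/1.349)·J^(−1/5) (modified Silverman,
  φ = 1 by default), argmax located on a 512-point grid spanning the
  ratios ± 3 bandwidths (grid size configurable).  Zero bandwidth (all
  ratios identical) returns the common ratio.  Consistent when the
  largest homogeneous cluster of SNPs is valid.  Bootstrap SE as above.
* **Heterogeneity** — Cochran's Q about the fitted slope (and intercept,
  for Egger), df = J−1 (J−2 for Egger), I² = max(0, (Q−df)/Q)·100.
  Wald-ratio residuals omit the θ²σ²_X term from their variance, so Q/df
  sits above 1 even without pleiotropy whenever instruments are finite-
  strength — visible in the simulated suites and in real data alike.
* **Instrument strength** — mean F = mean((β̂_Xj/σ_Xj)²); the mean-z²
  form is an assumption (the usual single number reported with summary-
  data MR), logged as weak below 10.
* **p-value floor** — two-sided p-values are floored at the smallest
  positive double rather than printed as 0; `log10_pvalue` reports the
  exact exponent via the normal log-survival function.

## Harmonization

Outcome effects are re-expressed per copy of the exposure's effect
allele.  Label swaps flip the outcome beta and complement its EAF;
strand complements (including complement-plus-swap) are resolved
deterministically for non-palindromic SNPs — dropping them instead would
discard recoverable data, so this package resolves them.  Palindromic
(A/T, C/G) SNPs cannot be resolved from labels: under the default
`infer_by_eaf` policy the strand is inferred from allele frequency
unless either study's EAF lies inside (0.42, 0.58), in which case the
SNP is dropped; `drop_all` removes them outright.  Every drop carries a
reason string.  Duplicated SNP ids keep the lowest-p row.  Instrument
selection uses strict p < 5·10⁻⁸.

LD proxies come from a user-supplied (SNP, proxy, r²) table — computing
r² from a reference panel is out of scope.  A substituted record keeps
the original SNP's exposure statistics but adopts the proxy's identifier
and the outcome file's alleles/EAF: without phased haplotypes the
proxy's relative orientation is unknowable, and at r² > 0.8 the
frequency-matched orientation is assumed.  Substitutions are flagged
`proxy_used` through to the harmonized table.

## Multivariable MR

The union of the single-exposure instruments is harmonized to a common
effect allele per SNP (first exposure carrying the SNP sets the
reference); SNPs missing any exposure's effect, missing from the
outcome, or unalignable are dropped with a log entry.  The estimator is
the zero-intercept weighted regression of β̂_Yj on the K exposure-effect
columns (weights 1/σ²_Yj); coefficient k is the direct effect of
exposure k.  SEs are inflated by √max(1, Q/(J−K)).  A design with
condition number above 10⁸ raises a collinearity error naming the
near-collinear exposure pairs (joint adjustment for strongly related
exposures is refused rather than silently returned; `allow_collinear`
skips the guard).  Conditional instrument strength per exposure uses the
Sanderson–Windmeijer Q-form: regress exposure k's effects on the others
with weights 1/σ²_Xkj and set F_k = Q_k/(J−K+1).

## Observational glycation-gap pipeline

Inclusion: age 18–65 inclusive, fasting glucose < 7.0 mmol/L, HbA1c
< 6.5%, hemoglobin inside the sex-specific normal range, optional
exclusion of recent diabetes-clinic attendees via a boolean column.  The
hemoglobin normal ranges are not part of the published inputs; defaults
are 130–170 g/L (male) and 120–160 g/L (female), overridable — the
filter logic, not the bounds, is what the tests pin down.  Exclusions
are tallied under the first matching reason in a fixed order.

Glycemic classification: normoglycemia = HbA1c < 6.0% and FG < 6.0
mmol/L.  The default `either` rule labels everything else (within the
filtered ranges) pre-T2D, so the two classes partition the cohort —
matching the arithmetic of a two-group cohort table; the conjunctive
`both` rule is available for sensitivity and yields an `indeterminate`
third label.

TGI = ln(TG[mg/dL] · FG[mg/dL]/2), with mmol/L inputs converted by 88.57
and 18.  (The triglyceride factor is the standard mmol/L→mg/dL
conversion; a source describing it as "mg/L" is read as a typo.)
Predicted HbA1c is a linear calibration on fasting glucose; the package
default equation is (4.163, 0.172) %/(mmol/L), and `fit_predicted_hba1c`
refits it per cohort with age/sex adjustment, exposing both the full fit
and the FG-only reduced equation.  Gap computation uses the FG-only form
by default: the gap is meant to capture non-glycemic deviation, and the
FG-only equation reproduces the published stratum medians, which the
age/sex-adjusted coefficients (not published) cannot.  Glycation gap =
measured − predicted HbA1c.

Stratified OLS of gap on TGI runs over five strata (pre-T2D,
normoglycemia, and HbA1c bands <5, 5–5.4, 5.5–5.9 within normoglycemia);
strata under 20 records are skipped.  The same machinery regresses
hemoglobin on TGI.  Diagnostics export plot-ready tables (Blom-scored
normal Q-Q of standardized residuals with the Q-Q correlation, residuals
vs fitted, residuals vs TGI) plus a Wald–Wolfowitz runs test on residual
signs ordered by fitted values as a curvature detector; no rendering.

### 0.632 bootstrap validation

Each replicate refits the linear model on a bootstrap resample and
evaluates on the out-of-bag records; corrected R², MSE and calibration
slope blend apparent and out-of-bag values as 0.368·apparent +
0.632·mean(oob).  Optimism = apparent − corrected R², flagged above 0.1.
Slope shrinkage = 1 − corrected calibration slope.  The g-index is
Gini's mean difference of model predictions; its corrected value is the
spread of the linearly recalibrated model, slope_corrected · g_apparent,
so it decreases exactly when the model overfits (a naive 0.632 blend of
out-of-bag prediction spreads moves the wrong way, because coefficient
noise inflates the spread of overfit models' predictions).  Calibration
slope and g-index are unstable when predictions barely vary (near-zero
R²) — they are reported but should not be over-read there, which is also
why the validation tests assert on optimism.  Default 200 replicates,
seeded; empty out-of-bag sets are redrawn and logged.

## Synthetic data: what it emulates, what it does not

**GWAS generator.**  Per SNP: MAF ~ U(0.05, 0.5); standard errors follow
the standardized-trait approximation se ≈ 1/√(2·maf·(1−maf)·n) with
n = 150,000 (exposure) and 400,000 (outcome) by default — the scale of
the consortium studies this stands in for.  True instrument strengths
are |z| = z_min + |N(0, z_spread)|, expressed per exposure-increasing
allele (the convention for published instrument panels; directional
pleiotropy is directional relative to that orientation).  Outcome means
are θ·γ_j + α_j with α_j from one of four pleiotropy models (none /
balanced / directional / InSIDE-violating with configurable
corr(α, γ)); an `invalid_fraction` of SNPs gets its Wald ratio shifted
by a gross offset for robustness scenarios.  Observed betas add sampling
noise; p-values are exactly 2·Φ̄(|β/se|), floored at the smallest
positive double.  `ensure_significant` redraws observed exposure effects
until genome-wide significant, emulating post-selection instruments.
Allele bookkeeping is realistic: 20% palindromic SNPs by default, and
the outcome file randomly swaps labels (30%) and/or reports the opposite
strand (30%), with small EAF noise, so harmonization is exercised on
every run.  Not emulated: LD between SNPs, winner's-curse bias beyond
the significance-conditioning, multi-ancestry structure, sample overlap.

Preset strengths: `fi_hb_like` uses (z_min, z_spread) = (8, 2) — a
realistic genome-wide-significant panel with mean F near 90 — and at
this strength every ratio-based estimator shows the known
weak-instrument dilution (MR-Egger most, roughly in proportion to its
1/I²GX factor).  The `strong_instrument` preset uses (80, 40), chosen by
a pre-registered sweep over (8,2), (15,4), (25,6), (40,15), (60,25),
(80,40) as the first regime (with margin) in which all five estimators'
200-replicate mean is within three Monte-Carlo standard errors of θ —
i.e. where the NOME assumption holds to the resolution of the test.
Estimator-consistency checks therefore run on `strong_instrument`;
passing them says the estimators are implemented correctly, not that
they are unbiased at realistic instrument strength (they are not, and
`fi_hb_like` shows it).  `weak_instrument` (z_min = 1) sits below F = 10;
`median_robust` makes 40% of SNPs grossly invalid; `null` sets θ = 0.
Type-I calibration is asserted for the fixed-effect IVW z, which is
exactly standard normal under this generator's null; the default
multiplicative random-effects model is conservative by construction
(the max(1, ·) floor only ever inflates).

**Cohort generator.**  Stratum membership is binomial with pre-T2D
probability 0.144.  Within each stratum, fasting glucose, triglycerides
and HDL are log-normal calibrated to the published stratum medians and
IQRs; age is truncated normal; sex is Bernoulli at the published mix.
HbA1c is built structurally as predicted(FG) + gap with gap =
intercept_s + slope_s·TGI + N(0, sd_s), using the published stratum
regression coefficients (−0.087, 1.77) and (+0.023, 0.14) as generator
truth and noise SDs (0.18, 0.33) calibrated to the published gap IQRs.
Hemoglobin is 129.1 + 1.88·TGI + N(0, 13) g/L (intercept placed so the
healthy median is 145 g/L at the healthy median TGI), clipped to a wide
physiologic band that essentially never binds.  Records are rejected and
redrawn until they satisfy their stratum's defining thresholds — the
same truncation that defines the strata in real data, where membership
is itself a function of the measured values.  Consequences worth
knowing: pre-T2D fasting glucose medians shift slightly above the
log-normal target; the narrow HbA1c bands inside normoglycemia acquire
negative gap-on-TGI slopes (conditioning on a narrow HbA1c window plus
the FG term forces it), so the published positive band slopes are *not*
generator truths and are not asserted; and applying the sex-specific
hemoglobin filter truncates the outcome of the hb-on-TGI regression and
attenuates its slope below 1.88 — truth-recovery tests therefore run on
the unfiltered generated cohort.  Not emulated: joint calibration to
every published IQR simultaneously, age/sex structure in glycemia,
post-prandial glucose, medications, repeat visits.

## Problem sizes

Simulation-based checks use 200 replicates of 49-SNP panels for
estimator means, 500 replicates for type-I error, cohorts of n = 7,600,
and 100–200 bootstrap replicates for validation — sizes at which every
asserted quantity's Monte-Carlo error is far below its tolerance while
the whole suite runs in seconds.

## Known limitations

No MR-PRESSO/contamination-mixture/robust-regression variants, no
Steiger filtering, no MVMR-Egger or median-based MVMR, no LD clumping or
reference-panel r² computation, no liftover, no figure rendering (tables
only).  The weighted-median/mode ratio SEs use the first-order delta
method; bootstrap SEs are parametric (normal sampling of the betas), not
data-resampling.  The interface is the Python API plus the `examples/`
scripts; no command-line entry points are shipped.
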