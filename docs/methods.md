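# Methods

`telomr` implements the analytic pipeline for studying the relation between
genetically predicted leukocyte telomere length (LTL) and cancer risk or
mortality: instrument quality metrics, weighted genetic risk scores (GRS),
two-stage regression with FDR control, a two-sample Mendelian randomization
(MR) estimator suite with sensitivity analyses, and Monte-Carlo power
evaluation. This note records the models, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## Instrument panel and orientation

The exposure instruments are 17 independent index SNPs from a European LTL
GWAS of n = 78,592, shipped as a tab-separated fixture
(`telomr/data/ltl_instrument_panel.tsv`) with per-allele effects on LTL in SD
units. The published table is on the *longer*-LTL scale;
`flip_to_shorter` negates every beta so that positive effects mean shorter
telomeres, which is the orientation all downstream analyses use. The flip
is guarded against double application and has an explicit inverse.

Instrument strength uses the squared Wald statistic F = (β/se)² and the
one-regressor identity PVE = F/(F + n − 2) for the fraction of exposure
variance explained. Both formulas reproduce every per-SNP value printed in
the source table (F to one decimal, PVE to three significant figures), the
panel totals (ΣPVE ≈ 1.37%) and the F summary (min 27.9, mean 63.3, max
205.4); that seventeen-fold agreement is why this PVE form was adopted.
Instruments with F < 10 are flagged as weak; the packaged panel has none.

## Harmonization and pleiotropy prescreen

Outcome GWAS summary statistics are aligned to the panel's effect alleles
per rsid. Swapped alleles negate the outcome beta; strand flips
(complement pairs) are folded into the same two cases for non-palindromic
SNPs; irreconcilable pairs are dropped with reason `allele_mismatch`, and
SNPs absent from the outcome with reason `missing` (no proxy search, which
matches how the original analysis handled a 15-of-17 situation).
Palindromic SNPs (A/T, C/G — four of the 17, including the TERC
instrument) are ambiguous to strand. The default policy `eaf_infer` keeps
them when both effect-allele frequencies lie outside the ambiguity band
[0.42, 0.58] and aligns by frequency concordance, else drops them; a
strict `drop` policy is also available. The band default reflects common
practice, and the frequency-based default was chosen because the TERC
palindromic SNP was evidently retained in the analysis this package
re-implements; it is a reasoned choice, not an established fact about that
analysis.

Before MR estimation, instruments nominally associated with the outcome
itself are removed when their outcome p-value falls below 0.05/k (k = the
current instrument count — the natural Bonferroni denominator when none is
stated). An emptied set is an error, not a silent null result.

## Genetic risk score

GRS_i = Σ_j G_ij β̂_j over the instruments present after QC, with G the
effect-allele dosage in [0, 2] and β̂ the shorter-LTL weights. Missing
dosages are mean-imputed at 2×EAF from the panel by default (`drop_sample`
is available). The score is standardized to mean 0, variance 1 within the
analysis sample; because the association Wald test is invariant to any
positive affine rescaling of the score, the standardization is a
presentation choice that fixes the effect unit at one SD of the score.
Zero-variance scores raise rather than divide by zero.

Genotype QC filters variants on call rate (< 0.95 removed), minor allele
frequency (< 0.01 removed) and Hardy–Weinberg equilibrium (exact p < 1e-4
removed). The HWE test is the exact conditional test on hard-called
genotype counts (dosages rounded for the test only), computed by the
standard recurrence anchored at the distribution's mode so it is stable at
biobank-scale counts; no mid-p adjustment. An exact rather than chi-square
test keeps behaviour sensible at the small sample sizes used in testing.
No installed package exposes this test, so it is implemented here and
checked against a full-enumeration oracle.

## Two-stage regression

Case-control outcomes: additive logistic regression of disease status on
the standardized GRS with an intercept and standardized covariates
(continuous covariates z-scored; binary left 0/1). Survival outcomes: Cox
proportional hazards with the Efron tie approximation. Fits are delegated
to statsmodels and lifelines respectively and are cross-checked against R
(`glm`, `survival::coxph`) to 1e-6 in the test suite. Non-convergence or
separation raises a `FitError`; there is no silent fallback estimate.

Effects are reported as OR or HR per SD of the score with Wald 95%
intervals exp(θ ± 1.96·se). Batches of outcomes (many cancers against one
shared control pool) form a single Benjamini–Hochberg FDR family;
case-control outcomes with fewer than 60 cases are excluded (the study's
inclusion threshold). Decision rule: FDR < 0.05 is significant, otherwise
p < 0.05 is suggestive, else null. Interaction tests refit the model with
a GRS×covariate product term and report its Wald test.

## MR estimators

All estimators act on the harmonized per-SNP pairs (β̂_jX, β̂_jY) with
their variances.

- **IVW (primary).** θ̂ = Σ w_j β̂_jY β̂_jX / Σ w_j β̂_jX², with
  w_j = var(β̂_jY)^{-1} and var(θ̂) = 1/Σ w_j β̂_jX². At k = 1 this reduces
  exactly (not merely numerically) to the Wald ratio β̂_Y/β̂_X with
  se = |se_Y/β̂_X|. The multiplicative random-effects variant inflates the
  SE by max(1, √(Q/(k−1))).
- **Cochran's Q.** Q = Σ w_j (β̂_jY/β̂_jX − θ̂)² with w_j = β̂_jX²/var(β̂_jY),
  referred to χ²(k−1). The battery uses fixed-effects IVW when Q's p > 0.05
  and random effects otherwise.
- **Weighted median.** Per-SNP ratios ordered; the estimate interpolates
  the weighted empirical CDF at cumulative weight 1/2, weights
  β̂_jX²/var(β̂_jY) (the inverse first-order ratio variance). SE by a
  seeded parametric bootstrap (default 1,000 resamples of both betas from
  their reported normals). Consistent while valid instruments carry more
  than half the weight.
- **Maximum likelihood.** β̂_jX ~ N(μ_j, se_jX²), β̂_jY ~ N(θμ_j, se_jY²);
  the nuisance μ_j profile out analytically, leaving a one-dimensional
  profile likelihood in θ maximized by Brent's method from the IVW start;
  SE from the numerically observed information. Agrees with fixed IVW in
  the absence of heterogeneity.
- **MR-Egger.** SNPs are first oriented so every β̂_jX ≥ 0 (required for
  the intercept's interpretation). Weighted least squares of β̂_Y on β̂_X
  with a free intercept, weights var(β̂_jY)^{-1}; SEs use multiplicative
  dispersion with the residual scale floored at 1 and a t reference on
  k − 2 df (the field-standard convention). The intercept's p-value is the
  directional-pleiotropy test; constraining the intercept to zero recovers
  the IVW slope algebraically.
- **Leave-one-out.** The estimator re-applied k times omitting each SNP.
- **MR-PRESSO.** Observed statistic: weighted RSS of each SNP's outcome
  effect about its leave-one-out IVW prediction. Null distribution:
  parametric simulation of both betas around the leave-one-out fits
  (default 1,000 draws, seeded), with the leave-one-out slopes recomputed
  per draw; global p is the rank-based tail probability with a +1
  correction so it is never zero. Per-SNP outliers are flagged at 0.05
  Bonferroni-corrected over k. Requires k ≥ 4.

`run_mr_battery` applies the decision rule: an association is *robust*
when the primary IVW, weighted-median and maximum-likelihood p-values are
all below 0.05, the Egger intercept shows no pleiotropy (p > 0.05), and
PRESSO flags no outlier; *null* when the primary IVW is non-significant;
*not_robust* otherwise. All point estimates are invariant to SNP ordering
and to joint per-SNP sign flips of (β̂_X, β̂_Y).

## Synthetic data

The generators reproduce the statistical structure the pipeline assumes,
so every stage is testable without restricted data.

- Genotypes: dosage ~ Binomial(2, maf) independently per SNP and sample
  (HWE, no LD), defaults at the packaged panel's 17 EAFs.
- Covariates: X1 ~ Bernoulli(0.5), X2 ~ N(0,1), each entering the linear
  predictor with effect 0.5. The generating design states only "one
  binary, one continuous"; these distributions are the package's choice.
- Case-control: η = GRS_std·θ + 0.5X1 + 0.5X2 over a 2,000,000-person
  population (desk-scale option smaller), y ~ Bernoulli(expit(η)), then
  exact case/control counts sampled without replacement.
- Survival: T = (−log U / (0.01·exp(η)))^(1/1) — a proportional-hazards
  Weibull (Bender-style inverse-probability transform) with shape 1 and
  scale 0.01. Censoring: exactly round(0.5·n) individuals chosen uniformly
  at random are censored at a time drawn uniformly on (0, T_i). The
  source description says only "50% censored at random"; exact-count
  censoring with uniform-on-(0,T) times is the package's reading, and the
  GRS is standardized within each replicate (population-level
  standardization differs negligibly at these sizes).
- Two-sample summary sets: true exposure effects |β| ~ U(0.03, 0.09) with
  random sign (the magnitude range of the packaged panel), observed betas
  with normal noise at fixed SEs (se_x = 0.006 panel-like, se_y = 0.01
  large-biobank-like); outcome means θ·β plus optional per-SNP
  heterogeneity, a directional pleiotropy intercept on the Egger-oriented
  scale, and a single outlier displaced by a stated number of outcome SEs.

Everything is seeded through `numpy.random.Generator`; identical seeds
give bit-identical outputs. What the generators do *not* emulate: LD
between instruments, population stratification, covariate-correlated
genotypes, confounder-driven (correlated) pleiotropy, informative
censoring, and case/control misclassification. Tests passing on this
synthetic structure therefore validate the estimators' algebra and
calibration under the stated model, not robustness to those real-data
complications.

## Power evaluation

Each grid cell simulates replicate cohorts, fits the adjusted model
(logistic or Cox), and reports the fraction of GRS Wald p-values below
α = 1.67e-3 (0.05 Bonferroni-corrected for 30 cancer types), with exact
Clopper–Pearson 95% intervals. One master seed spawns per-replicate
substreams, so any cell is reproducible in isolation. Cells with more
than 5% fit failures are marked invalid. Default grids: survival
n ∈ {100, 300, 500} × θ ∈ {0.05, 0.10, 0.20} at 1,000 replicates;
case-control cases ∈ {50, 100, 150} with the same effects. The GRS
effects are θ = 0.05/0.10/0.20 exactly (hazard or odds ratios of about
1.05/1.11/1.22 per SD), matching the generating description rather than
log(1.05) etc. The case-control default uses a 200,000-person population
with 30,000 controls for desk-scale runs; the full 2,000,000/300,000
design is available through options.

A known tension: with 150 events at n = 300 and a unit-variance score,
the Cox information bounds the θ = 0.10 cell's power near 2–3% at this α
(the harness reports ≈2.5%), noticeably below the ~10% sometimes quoted
for this design. The discrepancy is consistent with unstated differences
in censoring mechanism, score scaling, or test sidedness in other
implementations; the harness reports its cells with Monte-Carlo intervals
rather than asserting agreement.

## Numerical and degenerate-input conventions

- Exact reductions are exact: IVW at k = 1 returns the Wald ratio's
  floating-point values; Q at identical ratios is 0 with p = 1.
- Estimator preconditions (k ≥ 2 for Q/ML/LOO, k ≥ 3 for weighted median
  and Egger, k ≥ 4 for PRESSO) raise `MRError` rather than degrade.
- p-values from rank statistics carry a +1 correction; chi-square upper
  tails are floored at the smallest positive float so p ∈ (0, 1].
- Problem sizes in the test suite (replicate counts of 100–1,000,
  cohorts of 300–20,000) were chosen to give stable calibration checks at
  interactive cost; the acceptance drivers use the published 1,000
  replicates for the power cells.

## Known limitations

- No LD-aware instrument selection, proxy lookup, liftover, or genotype
  imputation; the panel arrives pre-selected and pre-imputed data are
  assumed.
- No multivariable MR, MR-RAPS, Steiger filtering, or contamination
  mixture; no competing risks or time-varying covariates in the survival
  arm.
- The weighted-median bootstrap and PRESSO are Monte-Carlo procedures;
  their p-values have simulation error of order 1/√n_sim.
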