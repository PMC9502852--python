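# Methods

## Scope and model

The package implements summary-statistics two-sample Mendelian
randomization with microbial-trait exposures, together with the
individual-level stages that produce the outcome-sample inputs: variant
QC, additive association screens, gene–diet and gene–sex interaction
scans, instrument selection and harmonization, the estimator battery, and
leave-one-out sensitivity analysis.

The structural model is the standard one: for instrument *j* with dosage
g<sub>j</sub> ∈ {0,1,2}, exposure A (a latent microbial-trait abundance,
SD 1) and outcome Y (fasting glucose, mg/dL),

    A = Σ_j α_j g_j + ε_A
    Y = θ A + Σ_j γ_j g_j + covariates + ε_Y

θ is the causal effect (mg/dL per SD of abundance) and γ_j are direct
(pleiotropic) SNP effects, zero for valid instruments. Instruments are
assumed mutually independent (no LD), which the generator enforces and
published mbGWAS hit lists approximate after clumping.

## Estimators

All estimators consume a table of harmonized instruments
(β̂_X, se_X, β̂_Y, se_Y per SNP, β̂_X ≥ 0 after orientation).

**IVW.** Weighted regression of β̂_Y on β̂_X through the origin, weights
1/se_Y²; identical to the inverse-variance-weighted mean of the Wald
ratios. The SE uses a multiplicative random-effects model: the
fixed-effect SE is scaled by √(Q/(J−1)) floored at 1, so heterogeneity
can widen but never narrow the interval. A `fixed_effect` flag disables
the scaling.

**MR-Egger.** The same weighted regression with a free intercept
(J ≥ 3, identified only when the β̂_X have spread). Slope = causal
estimate, intercept = average directional pleiotropy; dispersion floor
as above with J−2 degrees of freedom. `fit_intercept=False` collapses to
IVW exactly (a nesting identity the tests assert).

**Median family.** Ratio estimates are ordered; with normalized weights
w<sub>(j)</sub> the cumulative midpoints s_j = Σ_{k≤j} w_k − w_j/2 define a step
function inverted at 0.5 by linear interpolation (ties resolve by the
interpolation averaging its interval endpoints). Simple = equal weights,
weighted = inverse-variance ratio weights, penalized-weighted as below.
SEs come from a seeded parametric bootstrap (β̂_X, β̂_Y resampled from
their estimation normals; default 5000 draws, fewer than 100 rejected
unless `min_boot` is lowered explicitly).

**Penalization.** Each instrument's Cochran-Q contribution is referred
to χ²₁; weight j is multiplied by min(1, 20·p_j). The constant 20 is
configurable.

**Robust variants.** Tukey-biweight (c = 4.685) iteratively reweighted
M-estimation on the weighted regression, started from the weighted-LS
solution, with a Huber fallback on non-convergence (tolerance 1e−8, 200
iterations); the reported SE is floored at the fixed-effect SE. This is
M- rather than full MM-estimation: no S-estimation pre-stage is used, so
the fit inherits the weighted-LS starting point's breakdown behaviour —
adequate here because J is small and penalization handles gross
outliers first.

**Inference.** p-values are two-sided standard normal; 95% CIs are
estimate ± Φ⁻¹(0.975)·se. Heterogeneity: Cochran's Q about the IVW
estimate on the ratio scale (df J−1) and Rücker's Q′ about the Egger
line (df J−2), with per-SNP contributions reported.

**Leave-one-out.** J IVW refits each omitting one SNP plus the full-set
row. The `influential` flag formalizes the usual visual judgment: the
SNP with the largest omission shift is flagged if its own ratio opposes
the pooled sign **or** its Q-contribution p < 0.05. Both sub-criteria
are implemented as stated; under a homogeneous null the rule can flag a
benign SNP (the max-shift SNP often also has the largest Q
contribution), so the flag is a screening aid, not a test with
controlled type-I error.

## QC and screens

Variant QC applies, in a fixed order so removal counts are reproducible:
autosome check, MAF ≥ 0.01, Hardy–Weinberg χ²₁ p ≥ 1e−4 (plain 1-df
goodness-of-fit, no continuity correction, computed in all subjects),
call rate ≥ 90%. Surviving dosages are re-oriented to count the minor
allele. Missing genotypes stay missing — downstream fits are
complete-case per SNP, no imputation.

Association screens fit per-SNP additive OLS (glucose) or IRLS logistic
(diabetes) models via statsmodels, with named covariate sets
(`model1` crude … `model5` = sex+age+T2D+BMI+medication; the diabetes
screen uses sex+age+BMI). Linear p-values are t-based; logistic Wald
p-values normal. Separation yields a flagged, not raised, result.
Interaction scans fit the pooled model
y ~ dosage + modifier + dosage·modifier + covariates and report the Wald
p of the product term plus per-stratum refits (same covariates minus the
modifier, following the convention that strata models keep the pooled
adjustment set). Output ranks ascending by p with ties broken by |beta|
then rsID; Benjamini–Hochberg q-values are an optional, clearly labeled
extension column. A vectorized bulk scan (Frisch–Waugh–Lovell
residualization, algebraically identical to the per-SNP joint fit on
complete data) serves the genomic-inflation diagnostic
λ = median(χ²)/0.4549364 and Q–Q tables at tens of thousands of SNPs.

## Instrument selection and harmonization

Selection retains exposure associations with p ≤ 5e−8 (falling back to
1e−5 when fewer than three SNPs reach it), F = (β/se)² > 10,
outcome-sample MAF ≥ 0.10, and no membership in the pleiotropic
exclusion list (shipped with the MCM6/LCT lactase-region rsIDs, whose
microbiome associations run through milk intake; user-extendable). Every
removal is audited with a reason.

Harmonization maps both samples onto one effect allele: strand flips
(A↔T, C↔G) are applied when allele pairs only match after complementing;
the outcome beta is negated when reported on the other allele; finally
the pair is oriented so the exposure beta is non-negative
(abundance-increasing — "risk-increasing" has no meaning for an
abundance exposure, so the increasing direction is the convention).
Palindromic variants are kept only when both effect-allele frequencies
are known, fall outside the configurable ambiguity window [0.42, 0.58],
and agree on the side of 0.5; otherwise they are dropped with reason
`palindromic_ambiguous`. Harmonization never changes effect magnitudes
or SEs, and is idempotent (property-tested over randomized encodings).

## Synthetic data

The generator emulates an elderly Mediterranean outcome cohort and an
independent population-scale exposure sample:

| parameter | default | unit / note |
|---|---|---|
| n_subjects | 1020 | outcome cohort |
| glucose mean / SD | 120.1 / 38.3 | mg/dL; the SD is back-derived from SE 1.2 at n = 1020 |
| T2D prevalence | 0.465 | logistic on glucose (slope 0.04 per mg/dL), intercept root-found to hit the target |
| diet score | Binomial(14, 8.5/14) | 0–14 scale, dichotomized at ≥ 9 |
| age, BMI | 66.9 ± 6.4, 30.6 ± 5.1 | years, kg/m² |
| prop. male | 0.364 | glucose +9.9 mg/dL in men; age +0.2/yr, BMI +0.4 per kg/m² |
| medication | 0.80 among diabetics | the source population reports insulin (15%) plus oral drugs without a total; 0.80 is a realistic treated fraction |
| n_sample1 | 5959 | exposure sample size |
| instruments | 9, MAF ∈ (0.15, 0.45), α ∈ (0.11, 0.15) | per-allele effects in exposure-SD units → true z ≈ 5.5–5.8, p ≈ 4e−8..8e−9, F ≈ 30 |
| outlier effect | 12 mg/dL per allele | sized so omitting the outlier shifts the pooled IVW by ≈ 11 mg/dL |

Genotypes are Binomial(2, MAF) under Hardy–Weinberg; exposure summary
betas are drawn Normal(α_j, se_Xj) with the analytic OLS slope SE at
n_sample1; cohort glucose noise is scaled so the marginal SD matches the
target. A single master seed is split into named sub-streams (sample 1 /
genotypes / phenotypes), so the two samples share SNP identities and
alleles but no randomness, and regeneration with the same seed is
bit-for-bit identical. Ground truth (θ, α_j, MAFs, pleiotropy, seed) is
recorded verbatim.

What the generator does **not** model: microbial relative-abundance
compositionality (the MR chain only consumes summary statistics), LD
between instruments, population stratification, genotype missingness or
call errors, and real diet–genotype correlation. Passing tests therefore
certify the estimators and pipeline mechanics under the stated
assumptions, not robustness to those real-data complications.

## Numerical choices and known limitations

- Monomorphic SNPs raise an explicit degenerate-input error in single
  fits and are skipped (with pooled-model p still reported where a
  stratum is monomorphic) in scans.
- IVW/median estimators collapse to the single Wald ratio at J = 1;
  Egger requires J ≥ 3 and β̂_X spread.
- The dispersion floor max(1, σ̂) makes the random-effects SE exactly the
  fixed-effect SE on homogeneous data, so the nesting identities hold to
  machine precision.
- Ratio-based IVW carries first-order weak-instrument dilution of order
  θ/F̄ because E[β̂_X²] = α² + se_X². At the default instrument strength
  (F ≈ 30) this is a ~3% attenuation toward the null (≈ 0.8 mg/dL at
  θ = −25), visible in the Monte-Carlo recovery experiment; CI coverage
  stays nominal. No dilution correction is applied — the estimators
  reproduce the standard battery as defined.
- Whether published median-method SEs derive from bootstrap or analytic
  approximations varies by implementation; this package's bootstrap SEs
  are stable to ~3% at 5000 draws but are not expected to match analytic
  values digit-for-digit.

## Problem sizes used in the shipped experiments

Recovery: 500 replicates (tests) / 200 (acceptance script) of the full
two-sample simulation at J = 9, n₁ = 5959, n₂ = 1020, θ = −25. Null
calibration: 500 / 200 replicates at θ = 0, plus 1000 permuted-modifier
null SNPs for the interaction scan. Outlier detection: 200 / 100
replicates with one planted opposite-direction instrument. Inflation
diagnostic: a fully null scan of 50 000 (tests) / 30 000 (script) SNPs at
n = 1020. These sizes keep each experiment's Monte-Carlo error small
relative to the quantity it measures while completing in seconds to a
couple of minutes on one CPU.
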