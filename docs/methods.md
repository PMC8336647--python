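# Methods

`metabomatch` implements the statistical pipeline of a prospective nested
case-control metabolomics analysis: quality control and filtering of a
targeted (kit-based) metabolite panel, per-metabolite conditional logistic
odds ratios per SD of log concentration with permutation-based family-wise
error control, variable clustering with principal-component
representatives, and bootstrap-lasso (BoLasso) stability selection.  A
synthetic matched-cohort generator with known ground truth makes every
stage testable end to end without access to cohort data.

## 1. The matched design and the conditional likelihood

Subjects are 1:1 matched pairs (one incident case, one control drawn from
the same matching stratum: age band at blood collection, center,
menopausal status, fasting status, OC/MHT use at collection).  For a pair
with feature difference `d_i = x_case − x_control`, the conditional
likelihood is

```
L(β) = Π_i σ(βᵀ d_i),    σ(t) = 1 / (1 + e^(−t)),
```

i.e. intercept-free logistic regression on within-pair differences; all
stratum effects cancel.  Features are natural-log concentrations z-scored
over the analysis population, so `exp(β_j)` is the odds ratio per 1 SD of
log concentration (`OR_1SD`).  Adjustment covariates (standardized BMI, WC
or phase-standardized log C-peptide) enter as additional difference
columns.

**Estimation.**  Newton–Raphson with step halving; convergence when the
largest score component is below 1e-8 (followed by one final Newton step,
so the returned estimate is at quadratic-order accuracy — the discordant
pair closed form is reproduced to ~1e-9) or the step is below 1e-10;
maximum 50 iterations.  Covariance is the inverse observed information;
intervals are Wald, `exp(β ± 1.96·SE)`.  Complete separation is detected
as a standardized coefficient exceeding 15 with a non-vanishing score and
raised as an explicit error, never returned silently.

**Heterogeneity.**  For pair-constant subgroup variables, a
likelihood-ratio test compares per-level exposure slopes against a common
slope (`df = levels − 1`).  Variables that vary within pairs (BMI class,
WC class) use the unconditional fallback: ordinary logistic regression of
case status on exposure plus all matching factors as dummies, per stratum,
with a pooled interaction LRT.  Collinear dummy columns are pruned by a
greedy rank test before fitting.

**Restrictions.**  Sensitivity restrictions keep a pair only if it remains
complete: subject-level criteria (hormone use, fasting, diabetes) drop the
pair when either member fails; the diagnosis-lag criterion tests the case
only.  This pairwise completeness rule is forced by the conditional
likelihood; the source analysis reports restricted pair counts without
stating it.

**Covariate missingness.**  Continuous covariates missing in <5% of
subjects get the median, categorical ones the mode; categorical covariates
at or above 5% (or explicitly listed, e.g. ever-MHT) get an explicit
`missing` level; a continuous covariate ≥5% missing is an error unless the
user bins it first.

## 2. Panel QC and filtering

QC replicates of a reference plasma sample (default four per plate) yield
per-metabolite coefficients of variation: the intra-batch CV is
`100·sd/mean` of a plate's replicates, summarized as the **median across
plates** (the summary statistic is not stated by the source; the median
matches its use of median CVs elsewhere and is robust to one bad plate —
configurable); the inter-batch CV is `100·sd/mean` of the plate-level
means.  The exclusion cascade, with one reason per metabolite and fixed
precedence, is:

1. `not_detected` — QC mean zero/undefined or all measurements missing;
2. `cv_gt_threshold` — intra- **or** inter-batch CV strictly above 20%;
3. `out_of_range_gt_threshold` — strictly more than 20% of subject
   observations outside the measurable range (below LLOQ, above ULOQ, or
   below the plate-specific LOD for semi-quantitative analytes).

Thresholds are strict inequalities (a metabolite at exactly 20% survives)
and configurable.  Surviving below-range values are imputed at half the
LLOQ or half the plate LOD; an above-range value among retained analytes
is treated as an error because the cascade should have removed it.
Natural log is used throughout ("log-transformed" is base-free in the
source; per-SD odds ratios are invariant to the base).  z-scoring uses
cases and controls together (controls-only scaling would be an equally
defensible convention; the choice moves estimates by well under 1% and is
exposed by pre-subsetting the panel).

Derived features (metabolite sums and ratios, e.g. esterified-to-free
carnitine and short-chain acylcarnitines to free carnitine) are computed
on the linear concentration scale *before* the log transform and flow
through standardization like measured analytes.  Because the exact
composition of the source's sums and ratios is not published in the main
text, the shipped defaults follow standard acylcarnitine chain-length
conventions (esterified = all acylcarnitines except C0, short-chain =
C2–C5 species) and are fully user-overridable via a definitions file.

## 3. Stepdown minP

Under the per-pair null the case and control are exchangeable, so each
pair's whole difference vector can be sign-flipped independently without
changing the joint null — while preserving the between-metabolite
correlation.  The per-feature statistic is the score statistic at β = 0,

```
T_j = |Σ_i d_ij| / sqrt(Σ_i d_ij²),
```

a monotone transform of the univariate score test: p-values agree with
MLE-based permutation p-values but each permutation costs one matrix
product, which makes B = 10,000 routine.  The identity sign pattern joins
the Monte-Carlo ensemble, so the observed data are one of B+1 exchangeable
draws: raw p-values equal the add-one estimator
`(1 + #{T* ≥ T}) / (B + 1)` and the procedure is valid at finite B, not
just asymptotically in B.  The Westfall–Young
free stepdown orders features by p-value and adjusts `p_(j)` by the
permutation distribution of the minimum p over the tail set
`{(j), …, (m)}`, followed by a running maximum for monotonicity.  One
shared permutation stream across features is a correctness requirement of
minP and is enforced.  With ≤20 pairs all `2^n` sign patterns are
enumerated and p-values are exact.

Numerical convention: the stepdown comparison uses the same rank-based
estimator for observed and permuted statistics, so ties (atoms of the
sign-flip distribution) resolve identically in the raw and adjusted
computations; in Monte-Carlo mode an adjusted p-value can still sit up to
about half a boundary atom below the exact value at very small n — the
standard behavior of resampling minP implementations, and immaterial at
analysis scale where atoms have mass 1/B.

## 4. Variable clustering and representatives

Standardized variables are clustered agglomeratively under the latent
component criterion: a cluster's homogeneity is the leading eigenvalue λ1
of its correlation matrix, and each step merges the pair of clusters whose
merge loses the least total homogeneity `H = Σ λ1` (ties broken by lowest
feature index for determinism).  The representative of a cluster is its
unit-variance first-PC score, sign-oriented so its mean correlation with
members is positive; a singleton's representative is the standardized
variable itself.  `H` is non-increasing along the merge path and `H(k=1)`
equals λ1 of the full correlation matrix.

The number of clusters k is a user parameter (the source reports 64
clusters from 129 metabolites without a selection rule).  The default
follows an elbow rule: merge while each merge loses less than 5% of the
current total homogeneity.  Representatives can be residualized on BMI
(OLS on intercept + BMI), making downstream selection operate on
BMI-independent variation.

## 5. Penalized conditional logistic and BoLasso

The lasso objective on pair differences is

```
f(β) = (1/n) Σ_i log(1 + exp(−βᵀ d_i)) + λ‖β‖₁,
```

minimized by cyclic coordinate descent on the IRLS quadratic approximation
with warm starts along 100 log-spaced penalties from `λ_max` down to
`0.001·λ_max`, where `λ_max = max_j |Σ_i d_ij| / (2n)` is the analytic
smallest penalty with an all-zero solution (the unpenalized gradient at
zero is `−(1/(2n)) Σ_i d_i`).  An active-set strategy (solve on the
current support, then admit KKT violators from a full gradient scan)
keeps the path fast; solutions satisfy the KKT conditions to 1e-6
(`|g_j| ≤ λ` for zero coefficients, `g_j = −λ·sign(β_j)` for nonzero).
Non-convergence after 10,000 sweeps at any λ is an error naming the λ.

The penalty is chosen by K-fold cross-validation over **pairs** (a pair is
never split across folds) using held-out conditional binomial deviance
("error" is unspecified by the source; misclassification is available as an
alternative), with the one-SE rule: the largest λ whose CV deviance is
within one standard error (SD of fold deviances / √folds, at the minimum)
of the minimum.

BoLasso resamples the n matched pairs with replacement B = 100 times; each
replicate re-runs the 5-fold CV (folds seeded per replicate from the
master seed) and refits at its λ_1se; a variable's selection frequency is
the fraction of replicates with a nonzero coefficient, and the stable set
is frequency ≥ 0.90.  BMI enters through residualization of the
representatives only (whether the source also kept BMI as an unpenalized
covariate is unstated; an unpenalized-covariate mode can be emulated by
appending the BMI difference column and a zero-weight penalty is
deliberately not offered to keep the objective standard).

## 6. The synthetic matched-cohort generator

The generator emulates the study's data structure, not its biology:

* **Latent structure** — standardized log-concentrations follow a block
  factor model: within-block correlation ρ (default 0.6), optional global
  between-block correlation g ≤ ρ (default 0), defaults of 129 analytes in
  64 blocks (63 pairs + one triplet).  Concentrations are log-normal with
  per-analyte log-location ~ N(log 20, 1) and log-scale ~ U(0.35, 0.75).
* **Disease and matching** — a population of `population_factor × n_pairs`
  subjects (default 8×) gets case status from a logistic model on the
  standardized latent metabolites (planted per-SD log odds ratios) plus
  standardized BMI (default per-SD log-OR 0.45, matching the strong
  adiposity association of the emulated disease); controls are drawn at
  random without replacement from non-cases of the case's stratum.
  Because the disease model is logistic, the conditional probability that
  a given pair member is the case given both covariate vectors is exactly
  `σ(βᵀ(x₁ − x₂))`, so the conditional logistic estimator recovers planted
  per-SD effects without design bias — verified by the parameter-recovery
  simulations.  Matching failure (an exhausted stratum pool) is an
  explicit error naming the strata.
* **Plates and QC** — matched pairs share a plate (default 23 plates);
  each plate carries four QC replicates with multiplicative log-normal
  noise at a target CV (default 7%, the emulated panel's median) plus
  per-plate mean shifts (default 5%) that create distinct intra- and
  inter-batch CVs.
* **Censoring** — LLOQ/ULOQ are placed at configurable population
  quantiles (defaults 0/1 = no censoring); semi-quantitative analytes get
  per-plate LODs jittered ±10% around the LLOQ.  Raw simulated values are
  retained in the table — censoring is realized through the limits, range
  flags and half-limit imputation, mirroring how kit exports carry
  sub-LLOQ readings.
* **Covariates** — BMI ~ N(26, 4.5²) on the natural scale with optional
  planted metabolite correlations (solved through the latent correlation
  matrix so the joint covariance stays valid), WC correlated 0.8 with BMI,
  two-phase C-peptide, hormone-use/smoking/diabetes indicators with
  population-plausible frequencies, gamma diagnosis lag (mean ≈ 8.3 y,
  SD ≈ 4.5 y), and configurable per-covariate missingness.
* **Randomness** — one top-level seed; all sub-streams spawned
  deterministically from it; identical config + seed reproduces every
  output byte for byte.

What the generator does **not** emulate: incidence-density risk sets and
follow-up time (matching is stratified sampling — the analysis only needs
valid matched pairs), plate-position/drift effects beyond batch mean
shifts, multi-control matching, assay chemistry, and real biological
effect-correlation structure.  A green simulation test therefore
establishes statistical correctness of the estimators under the stated
data-generating assumptions, not biological realism.

The packaged 188-analyte QC fixture is engineered (deterministically, at a
fixed packaged seed) so the filter categories occur in fixed numbers: 31
analytes fully undetected, 8 with QC CVs far above threshold (target 50%),
20 with ~35% of observations below their limit, 21 retained analytes with
~8% below-limit values, 108 clean — so the cascade retains exactly 129.
Limits are placed between order statistics so the below-limit counts are
exact, not stochastic.

## 7. Validation experiments

`scripts/acceptance.py` recomputes, from scratch at a user seed: the
fixture filtering count (129); the empirical FWER of stepdown minP over
1,000 null cohorts (200 pairs × 30 metabolites in six ρ=0.5 blocks,
B=500), which must not exceed 0.05 beyond Monte-Carlo error; the
geometric-mean recovered OR over 500 cohorts of 853 pairs with planted
per-SD ORs 1.18 and 0.89 (the magnitudes of the leading positive and
inverse associations the pipeline is designed to estimate); and the
minimum BoLasso selection frequency among four planted OR-1.5 predictors
out of 64 BMI-residualized representatives at 853 pairs (100 bootstraps,
5-fold one-SE CV).  For the recovery runs the BMI effect is switched off
so the planted marginal and conditional effects coincide; with a BMI
effect present the marginal per-SD OR would shrink slightly through
logistic non-collapsibility, which is a property of the estimand, not an
estimator bias.

## Known limitations

* Only 1:1 matching is supported (no m:n conditional likelihood).
* No exact conditional logistic regression (exhaustive enumeration exists
  only as a test oracle).
* No plate-drift normalization; imputation is half-limit substitution only.
* The minP procedure offers no maxT variant and no FDR control.
* Heterogeneity LRTs assume the subgroup is non-informative for the
  matching beyond the matching factors themselves.
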