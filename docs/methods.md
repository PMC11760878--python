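# Methods

## The model

Two-sample MR treats genetic variants as instruments for an exposure X.
For variant j, let β̂_Xj (SE σ_Xj) be the per-allele association with X
from one GWAS and β̂_Yj (σ_Yj) the association with the outcome Y from a
second, non-overlapping GWAS.  Under the three instrumental-variable
assumptions — relevance, independence from confounders, and no direct
path to the outcome — each Wald ratio r_j = β̂_Yj/β̂_Xj estimates the
causal effect of X on Y, with first-order standard error
s_j = σ_Yj/|β̂_Xj|.

The two-step mediation design runs this machinery twice along the path
X → M → Y: stage 1 estimates B₁ (effect of the exposure on the mediator),
stage 2 estimates B₂ (effect of the mediator on the outcome, log-odds for
binary Y), and the mediated effect is the product of coefficients
B_m = B₁B₂ with the Sobel standard error
S_m = √(B₁²S₂² + B₂²S₁²), Z = B_m/S_m, and normal 95% CI B_m ± 1.96·S_m.
The delta-method S_m omits the S₁²S₂² term of the exact product variance;
with the moderate relative SEs typical of GWAS-scale stages the
difference is below 1% (a Monte-Carlo check in the test suite quantifies
it).

## Estimators

All five estimators consume the harmonized per-variant pair table.

- **IVW**: B = Σw_jr_j / Σw_j with w_j = 1/s_j²; fixed-effect
  SE = (Σw_j)^{-1/2}.  Under the multiplicative random-effects model the
  SE is inflated by max(1, √(Q/(k−1))) where Q is Cochran's Q; `auto`
  (the pipeline default) uses random effects when the Q test is
  significant at 0.05.
- **MR-Egger**: weighted least squares of β̂_Y on β̂_X *with intercept*,
  weights 1/σ_Yj², after orienting every pair so β̂_X ≥ 0 (the estimator
  is not orientation-invariant; the exposure-increasing-allele convention
  is standard).  The slope is the causal estimate, the intercept the mean
  directional pleiotropy; SEs carry the same multiplicative inflation
  floored at 1.
- **Weighted median**: the ratio at cumulative standardized weight 0.5,
  interpolating linearly between order statistics placed at their weight
  midpoints (so three equal-weight ratios give the middle one exactly).
- **Simple/weighted mode**: the maximizer of a normal-kernel density over
  the ratios on a 1000-point grid spanning their range, bandwidth
  φ·0.9·min(sd, IQR/1.349)·k^{−1/5} (φ defaults to 1); weights uniform or
  inverse-variance.  Identical ratios (zero bandwidth) return the common
  value.

Median and mode SEs use a parametric bootstrap (resample both effect
columns from N(observed, SE), default 1000 draws, seeded).  All p-values
are two-sided normal; for Egger this is a deliberate convention choice
(a t reference with k−2 df is the other common option and is slightly
more conservative at small k).

A direction is *called* causal when the IVW p-value is below 0.05 **and**
all five effect estimates share a sign; the call is risk or protective
according to whether the IVW OR exceeds 1.  No multiple-testing
correction is applied anywhere — the workflow is explicitly exploratory,
and the report tables carry everything needed to re-threshold.

## Instrument QC

Selection keeps variants with exposure p < 5×10⁻⁸, then greedily clumps
by p-value (ties broken by variant id) removing same-chromosome
candidates within 10,000 kb whose r² exceeds 0.001.  Without an LD
lookup, all same-window pairs are treated as linked (distance-only
thinning); this is exact for the synthetic data, whose SNPs are
independent and placed ≥25 Mb apart.  The per-variant F-statistic is the
squared Wald ratio (β/σ)², with the variance-explained form
r² = F/(F+n−2) derived from it; instruments require F > 10.  Confounder
exclusions match on variant id against a user-supplied annotation list
(the interface stands in for LD-trait web lookups, which are out of
scope, as is clumping against a genotype reference panel).  After
harmonization, variants with outcome p < 1×10⁻⁵ are removed.

Harmonization aligns on the exposure's effect allele, sign-flipping
swapped outcome records and resolving strand flips by base
complementation.  Palindromic variants (A/T, C/G) default to EAF
inference: kept only when both EAFs lie outside 0.5 ± 0.08, flipped when
the EAFs disagree in sign about 0.5; the `drop` policy discards them
outright.  The tolerance and the ambiguous band are policy defaults, not
facts about any particular source dataset.

## Sensitivity diagnostics

- **Cochran's Q** over the ratios, χ² with k−1 df.
- **Egger intercept test** at 0.05 for directional pleiotropy.
- **Outlier test** (MR-PRESSO-style): observed global RSS
  Σ_j(β̂_Yj − b_{(−j)}β̂_Xj)² with leave-one-out IVW slopes; the null
  distribution re-simulates β̂_Y from N(b_{(−j)}β̂_Xj, σ_Yj), default
  1000 draws.  Monte-Carlo p-values are (exceedances+1)/(n_sim+1) so they
  can never be exactly zero.  Per-variant terms are tested the same way
  with a Bonferroni threshold α/k; flagged outliers are removed before
  the estimators run.  An optional distortion report compares the IVW
  estimate before and after removal.
- **Steiger directionality**: instruments should explain more variance in
  the exposure than in the outcome; per-variant r² is recovered from F,
  summed per side, and compared via a two-sample z-test on
  Fisher-transformed √r².  For binary outcomes the same F-based r² is
  applied on the log-odds scale — an approximation, flagged as such.
- **Sample-overlap bias**: expected bias = overlap × assumed confounded
  effect / mean F (the bias-estimation-factor form used in the two-sample
  overlap literature), with type-I error
  P(|Z + bias/se_unit| > z_{0.975}).  All three inputs are explicit
  configuration, since none can be estimated from the summary data
  themselves.

## Stage-1 variants

Two stage-1 implementations are provided and labelled in the report.
True 2SLS needs individual-level data: regress X on instrument dosages,
then M on the fitted X (both with intercepts); the coefficient table
(intercept row, slope row, t with n−2 df, R²) comes from the second
regression.  When only summary statistics exist, the same report shape is
produced by an intercept-including weighted regression of mediator-side
on exposure-side per-variant effects (weights 1/σ²_M,j, t with k−2 df,
weighted R²).  The two agree asymptotically on data generated under the
model; a test checks that their gap shrinks between n = 2,000 and
n = 10,000.  Stage 2 is the IVW estimate on the mediator→outcome table;
the report records whether the fixed- or random-effects SE fed the Sobel
formula.

## Synthetic data

The generator draws independent biallelic SNPs (MAF uniform on
(0.05, 0.5), dosages binomial), splits them into exposure instruments
(effects γ_j ~ N(0, 0.1²) on X) and mediator instruments (direct effects
α_j ~ N(0, 0.1²) on M) — mirroring real two-step designs in which the
exposure and mediator have distinct GWAS hits — and builds
X, M with unit expected variance (noise variances are solved from the
variance budget; an infeasible budget raises).  The binary outcome is a
liability threshold with standard-logistic noise, so the per-SNP logistic
scan estimates log-odds effects on their natural scale; setting the
prevalence to `None` yields a quantitative outcome with unit normal
noise instead.  Directional pleiotropy (nonzero-mean direct SNP→outcome
effects) is injected on the exposure-increasing-allele orientation — the
orientation Egger regression uses — because a mean offset in raw allele
orientation with random-signed γ is balanced, not directional.
Confounding is a shared standard-normal latent added to both X and the
outcome; sample overlap shares a configurable fraction of individuals
between the exposure and outcome GWAS subsamples (the mediator sample is
always disjoint).

Per-SNP scans are closed-form simple linear regression for quantitative
traits and a vectorized Newton (IRLS) logistic regression for the binary
outcome (cross-checked against statsmodels in the tests); Wald p-values
use the normal distribution.  Default scale: 50 SNPs and 20,000
individuals per trait GWAS, giving mean single-SNP F ≈ 70 so that a
realistic share of instruments clears genome-wide significance.

What the generator does **not** emulate: LD between variants (it
produces the post-clumping state the estimators assume), case-control
ascertainment beyond prevalence thresholding, population stratification,
and allele/strand errors.  Passing tests therefore validate the
statistical machinery under the stated model, not robustness to those
real-data complications.

## Validation experiments

`experiments.py` fixes the study conditions used by the test suite and
the acceptance script:

- **Null calibration** (summary level, 1000 replicates, 50 SNPs):
  IVW on a true-null exposure→outcome pair, and Sobel with a true-null
  first stage (second stage effect 0.4), both reject at ≈5%; the outlier
  test's global p on clean data (200 replicates) stays near nominal —
  slightly above, because the observed leave-one-out RSS carries the
  slope-estimation variance the simulated null omits.
- **Recovery** (cohort level, 100 replicates, 50 SNPs, n = 20,000 per
  GWAS): the Sobel 95% CI covers the true mediated effect
  a×b = 0.3×0.4 = 0.12 in ≥93% of replicates.  Empirical coverage sits
  near 95% with a small downward push from non-collapsibility: the
  marginal per-SNP log-odds that stage 2 estimates are attenuated by
  ≈2–3% relative to the conditional b.
- **Overlap pattern** (cohort level, 150 replicates per level, 100
  weakish instruments with mean F ≈ 5, confounder effect 0.8,
  quantitative outcome): the empirical type-I error of IVW under the
  confounded null rises monotonically over overlap ∈ {0, 0.5, 1} —
  weak instruments transmit the confounded association in proportion to
  the shared-sample fraction.
- **Determinism**: two pipeline runs with the same configuration and
  seed produce byte-identical report files (all randomness flows from
  per-component seeds derived from the global seed; TSVs are written
  with a fixed float format).

## Known limitations

- Distance-only clumping is conservative when no LD panel is supplied.
- The naive stage-B standard error of the 2SLS coefficient ignores
  first-stage estimation noise (slightly conservative in the settings
  tested).
- The Steiger r² approximation on the log-odds scale understates
  outcome-side variance explained for rare outcomes.
- The overlap-bias formula is a first-order planning tool, not an
  estimator; its confounded-effect input is an assumption.
- Bundled published coefficient tables are carried to their printed
  precision only; recomputed products are compared at 3 significant
  figures.
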