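# Methods

This note documents the statistical models implemented in `triangmr`, the
choices made where conventions diverge, what the synthetic-data generators
do and do not emulate, and known limitations.

## Harmonization

Two-sample MR requires exposure and outcome effects on the same effect
allele. For each shared variant the outcome row is matched to the exposure
alleles directly, after an allele swap (beta negated, EAF complemented),
or after strand complementation. Palindromic variants (A/T, C/G) carry no
strand information in their alleles; orientation is inferred from allele
frequency, and variants whose minor-allele frequency exceeds
`palindromic_eaf_limit` (default 0.42) on either trait are dropped as
unresolvable. Variants with missing frequency are dropped only when
palindromic. Matching is by variant id; kept + dropped always equals the
intersection, and harmonizing an already-aligned pair is a no-op.

## Instruments

Instruments are variants with exposure P < 5×10⁻⁸, greedily clumped so no
retained pair has LD r² ≥ 0.001 within 10,000 kb (all thresholds
configurable; p-value ties break by variant id so selection is
deterministic and order-invariant). Variants absent from the LD panel are
treated as independent, with a warning. Per-variant strength uses
R² = 2·EAF·(1−EAF)·β² and F = β²/se², summed over the set; a minimum or
mean F ≤ 10 raises a weak-instrument flag but never filters automatically,
since the F > 10 rule is descriptive. Summed R² on the log-odds scale can
exceed 1; this is reported with a warning rather than treated as an error.
A confounder filter removes instruments annotated (in a local
phenome-scan-style table) to any listed confounder trait at proxy R² ≥ 0.8
and P ≤ 5×10⁻⁸.

## MR estimators

All ratio-based estimators use first-order Wald-ratio SEs
(se_ratio = se_Y/|β_X|), ignoring exposure-side noise; MR-RAPS is the
member of the suite that models exposure noise explicitly. Significance is
nominal 0.05 with no multiple-testing correction (a Bonferroni option
exists behind a flag).

- **IVW (primary).** Precision-weighted mean of Wald ratios; the
  multiplicative random-effects SE is the fixed-effect SE scaled by
  √max(1, Q/(m−1)), so it never undercuts the fixed-effect SE. P-values
  use the normal reference. The floor makes the headline test mildly
  conservative by construction; exact p-uniformity under the null holds
  for the fixed-effect variant (reported in `extras`), which is also what
  the power calculation and its Monte-Carlo oracle target.
- **MR-Egger.** Weighted regression with intercept after orienting all
  exposure betas non-negative; the intercept estimates average directional
  pleiotropy. SEs carry √max(1, Q′/(m−2)); p-values use a t reference
  with m−2 df.
- **Weighted median / penalized weighted median.** Weight-interpolated
  50th percentile of the ratios with inverse-variance weights;
  penalization multiplies each weight by min(1, 20·q_j), q_j the upper
  χ²₁ tail of the variant's Cochran-Q contribution. The SE comes from a
  seeded parametric bootstrap under the fitted common-effect model:
  resamples are centered at the estimate with the per-variant ratio SEs.
  Centering at the observed ratios instead would add the between-variant
  spread on top of the sampling noise and systematically overstate the SE
  (empirically ~0.02–0.03 type-I error instead of ~0.05); with the fitted
  centering, the bootstrap SE matches the empirical sampling SD to within
  a percent. Under gross instrument invalidity the SE does not inflate,
  but the point estimate's robustness (up to 50% invalid weight) is the
  quantity of interest there.
- **MR-PRESSO.** Observed residual sum of squares from leave-one-out IVW
  slopes; the null distribution re-simulates both traits' betas from
  their sampling distributions under the leave-one-out fits (default
  1000 simulations). The global p is the fraction of simulated RSS at or
  above the observed; per-variant outlier p-values are Bonferroni-tested
  at 0.05. When the global test fires, the headline estimate is IVW on
  the outlier-free set — the standard reporting convention — with the raw
  estimate and a distortion p (null distribution from removing random
  same-size variant subsets) kept in `extras`.
- **MR-RAPS.** Solves the profile score Σ ψ(t_j)·∂t_j/∂β = 0 with
  t_j = (β_Yj − β·β_Xj)/√(se_Yj² + β²·se_Xj² + τ²); τ² (overdispersion
  from systematic balanced pleiotropy) is profiled out by matching the
  second moment of ψ(t)·t when enabled. ψ is the identity or a Huber
  score (c = 1.345). Root-finding is bracketed (expanding symmetric
  bracket) and deterministic. The SE is the sandwich B/A² of the profile
  score; because the sandwich runs ~5–10% below the empirical sampling SD
  at m ≈ 50, p-values use a t reference with m−1 df, which restores
  type-I error to ~0.05.
- **Steiger.** r² per trait is Σ 2·EAF·(1−EAF)·β², applied on the
  log-odds scale for binary traits (a documented approximation — the same
  formula is conventional for reporting instrument R² on binary traits);
  z compares Fisher-transformed √r² values with variance
  1/(n₁−3) + 1/(n₂−3). Exactly equal r² gives z = 0, p = 1 and an
  indeterminate flag.
- **MVMR.** Outcome betas regressed on the matrix of exposure betas
  without intercept, weights 1/se_Y²; instruments are the union of
  per-exposure genome-wide-significant variants jointly clumped. SEs
  carry √max(1, Q/(m−k)). Conditional instrument strength is reported as
  the weighted residual mean z² after projecting each exposure's effects
  on the others — an approximation to the conditional F statistic, noted
  as such in `extras`. Rank-deficient exposure matrices raise an error
  naming the collinear exposures.

## LD-score regression

Heritability: weighted regression of z² on ℓ with free intercept,
h² = slope·M/n. Genetic covariance: regression of z₁z₂ on ℓ, free
intercept absorbing sample overlap, cov_g = slope·M/√(n₁n₂);
r_g = cov_g/√(h₁²h₂²). Weighting is two-step: an unweighted pass, then
heteroskedasticity weights 1/pred² for the h² regressions and
1/(pred₁·pred₂ + pred_cov²) for the covariance regression, all predictions
from the first pass (clamped below at 0.1). This weight choice makes
r_g(trait, itself) exactly 1 and the estimator exactly symmetric in its
two traits, both of which are asserted in tests. Standard errors come
from a delete-a-block jackknife over contiguous variant blocks (default
200, configurable down for small panels) with weights held fixed, the
standard practice. Pairs are filtered to a reference variant list and
MAF ≥ 0.01 before regression. A pair is reported `na_low_heritability`
instead of given an r_g when either h² estimate is non-positive; an
optional z-score floor (h²/se < 1) widens the NA rule, since "too low
heritability" is not otherwise quantified. |r_g| > 1.25 triggers an
overshoot warning; truncation to [−1, 1] is opt-in.

## Colocalization

Per-variant log Wakefield ABFs: 0.5·log(V/(V+W)) + 0.5·z²·W/(V+W), with
V = se² and W the squared prior effect SD (default 0.2 per trait, the
scale conventional for log-odds effects). Hypothesis evidence under "at
most one causal variant per trait": H₀ = 1, H₁ = p₁·ΣABF₁,
H₂ = p₂·ΣABF₂, H₃ = p₁p₂·(ΣABF₁·ΣABF₂ − ΣABF₁ABF₂), H₄ = p₁₂·ΣABF₁ABF₂,
with priors p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵ (the method's convention;
prominently configurable and echoed in every posterior object). All sums
run in log space with log-sum-exp — plain arithmetic overflows doubles
near |z| ≈ 40 — and H₃ uses a guarded log-difference that returns zero
evidence for single-variant regions. Regions are ±500 kb windows around
each instrument; overlapping windows are deliberately not merged, the
pair-level result is the unweighted mean of PPH₄ across regions, and the
shared-variant call is mean PPH₄ > 0.75. Averaging PPH₄ over regions is
an unusual aggregate (one strong colocalizing locus among many null
instrument regions is diluted), so the per-region table is always
emitted for inspection.

## Power

For a binary outcome the IV Wald test has approximate non-centrality
ncp = n·cf·(1−cf)·R²_xz·log(OR)², giving power
Φ(−z_{1−α/2} + √ncp) + Φ(−z_{1−α/2} − √ncp). The correctness criterion is
a Monte-Carlo oracle — simulate the two-sample pipeline at the stated
parameters and count rejections of the fixed-effect IVW Wald test — rather
than agreement with any particular published algebra. Power is α at
OR = 1 or R² = 0 and symmetric in OR ↔ 1/OR.

## Triangulation

LDSC and MR calls are significant at p < 0.05 with a direction; the
colocalization call (mean PPH₄ > 0.75) carries none. The mapping to
patterns 1–10 / explanations i–ix is total and pure; an LDSC result that
is unavailable from low heritability is treated as not significant and
flagged, since unavailability is not evidence of correlation. The MR call
defaults to the primary IVW result; a pleiotropy-adjusted source
(confounder-filtered/outlier-corrected) is selectable, and when primary
and adjusted calls disagree the verdict carries an `adjusted_attenuated`
flag. Risk of bias aggregates eight user-supplied domain judgments by a
worst-domain rule, coercing missing domains to moderate (no information);
the domain criteria themselves are user inputs, not encoded.

## Synthetic data

Generators draw directly on the summary-statistic scale; no
individual-level genotypes exist.

- **LD panels** are block-diagonal AR(1): within a block
  r(i,j) = ρ^|i−j|, zero across blocks, positive semi-definite by
  construction. Real human LD (variable block sizes, long-range
  structure, MAF-dependent correlation) is not emulated.
- **MR scenarios** place instruments in distinct blocks so independence
  holds by construction. True exposure effects are N(0, scale²) with
  scale 0.08, truncated away from zero (|γ| ≥ 6·se_X) so every instrument
  is relevant; with the default n = 50,000 this gives per-variant F
  statistics of order 10²–10³ and instrument counts (default 50) in the
  range typical of consortium autoimmune-disease GWAS. Summary betas are
  the LD-propagated true effects plus independent Gaussian noise with
  se = 1/√(2·maf·(1−maf)·n), scaled by cf·(1−cf) for binary traits
  (default outcome case fraction 0.2) — the standard log-odds variance
  approximation used when distributing case-control summary statistics.
  Directional pleiotropy is defined relative to the exposure-increasing
  allele (α multiplied by sign(γ)); otherwise random allele coding would
  cancel the configured mean. Confounding routes 20% of instruments
  through a latent trait affecting both sides, and those instruments are
  annotated under real confounder names (body mass index, smoking, …) so
  the filter is exercised end to end.
- **Coloc regions** build marginal z-scores as R·λ plus correlated noise
  (Cholesky of R), with the causal non-centrality (default 8) at
  configured indices; the `distinct` configuration splits the region into
  two independent halves so the two causal variants are in linkage
  equilibrium.
- **LDSC datasets** draw LD scores as 1 + Gamma(2, 30) (right-skewed,
  mean ≈ 61) and z-pairs jointly normal per SNP with the model variances
  and covariance, including an optional sample-overlap intercept.

Because noise is drawn independently per variant given the LD-propagated
means, long-range correlated sampling error between nearby variants is
not represented; tests passing on these generators therefore validate the
estimators' algebra and calibration under their stated models, not
robustness to real-data artifacts (population stratification, assortative
mating, allele-frequency mismatch between panels).

## Problem sizes and seeds

The default validation scales — 2000 replicates for null calibration and
Kolmogorov–Smirnov uniformity, 1000 for recovery/coverage, 500 for
intercept/direction/MVMR checks, 200 for PRESSO outlier detection, 100
for coloc and r_g classification rates, M = 20,000 SNPs for LDSC — keep
the full suite and the acceptance script around a minute each on one CPU
while leaving Monte-Carlo error well inside the asserted bands. All
stochastic procedures take explicit seeds and are bit-reproducible given
(seed, n_sim); the pipeline derives per-pair, per-stage child seeds from
the config seed, so identical configs give byte-identical outputs.

## Known limitations

- No CAUSE, mode-based, or contamination-mixture estimators; no
  SuSiE-style multi-causal colocalization; no partitioned LDSC.
- No genome-build liftover, multi-allelic variants, or VCF input.
- Steiger r² and summed instrument R² use the quantitative-trait formula
  on the log-odds scale; both can exceed their nominal ranges on strongly
  ascertained case-control data and are flagged rather than corrected.
- The PRESSO distortion test uses random same-size subset removal as its
  null; this is a simplification of the original bootstrap scheme.
- Power is implemented for binary outcomes only.
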