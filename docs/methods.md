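# Methods

This note documents the statistical models implemented in `triagen`, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort model (`synthio`)

**Genotypes.** Haplotypes are drawn per LD block from a first-order
autoregressive latent Gaussian (corr(i, j) = block_r^|i−j|) thresholded at
the allele-frequency quantile; two haplotypes per individual sum to a 0/1/2
dosage. This yields Hardy–Weinberg genotypes with tunable pairwise r²,
sufficient for clumping and lead-extraction tests; it is not a realistic
human LD map. Each block sits on its own synthetic chromosome with 1-based
positions every 10 kb. Base allele frequencies are a property of the
architecture (fixed seed), so cohorts drawn with different seeds share a
frequency spectrum; `ancestry_fst_like` adds per-cohort logit-normal jitter
to emulate ancestry-specific frequencies.

**Risk haplotype.** Two variants in one block define the haplotype; a copy is
counted when one chromosome carries the effect allele at both positions
(0/1/2 copies per subject). Per-copy log-odds effects act on the mediator
(default 1.1, i.e. OR ≈ 3 per copy on a dementia-like trait) and directly on
the outcome (default 0.131, OR ≈ 1.14, matching the scale of a one-copy
direct effect on delirium). The mediator transmits to the outcome with
log-OR 2.0 (dementia is a strong delirium risk factor), so part of the
haplotype effect is mediated — the fraction is recoverable by `mediate`.

**Outcome and covariates.** A single logistic draw per subject: logit P(Y=1)
= c₀ + β_direct·hap + γ·M + 0.05·(age−60) + 0.10·sex + 0.01·(BMI−27) +
Σβ_k·protein_k; the intercept c₀ is solved (Brent) so the expected case
fraction equals the requested prevalence given the realized predictors.
There is no time-to-event process; `follow_years` and an onset time are
drawn only to support the ">1 year after baseline" incident-case rule.
Ages are N(60, 8), BMI N(27, 4), sex Bernoulli(1/2). The single age column
is used for cases and controls alike.

**Proteins.** Standardized true level = Σ cis-effects · standardized dosage +
Gaussian noise (variance topped up to ~1). Cis variants are constrained to
±1 Mb of the protein's nominal gene (both ends inclusive). Disease effects
are per-SD log-ORs entering the outcome model. Missingness is
missing-completely-at-random per entry (default 20%); no batch structure,
assay noise floor, or limit-of-detection censoring is modelled, so passing
tests demonstrate statistical correctness of the pipeline, not robustness to
Olink-specific artifacts.

**Determinism.** One master seed is split into independent per-stage streams
(genotypes, covariates, mediator, outcome, proteins, missingness), so equal
seeds give bit-identical cohorts and bit-identical files on disk.

## Association scans (`assoc`)

Per-variant maximum-likelihood logistic regression (Newton–Raphson with
step-halving; Wald standard errors from observed information), covariates
plus optional conditioning columns; per-variant complete-case handling of
missing dosages. Perfect separation is flagged (|β| > 25 or all fitted
probabilities pinned) and the p-value left missing — no Firth penalization.
Quantitative traits use OLS. The Hardy–Weinberg test is the exact
conditional test by full enumeration, two-sided by summing configurations no
more probable than the observed one, without a mid-p correction. QC reads
"more than five minor alleles" as strict MAC > 5 in each arm. Genomic
control is λ = median(χ²₁)/0.45494; the scan engine is cross-checked against
statsmodels to 10⁻⁶ in the tests. Odds-ratio intervals use the delta-method
form OR ± z·se·OR (deliberately not exp(β ± z·se)).

## Meta-analysis (`metagwas`)

Fixed-effects inverse variance with per-study genomic control applied before
pooling (λ floored at 1); a meta-level second correction exists behind a
flag but is off by default. Allele harmonization matches (ea, oa) directly
or swapped with a sign/frequency flip; palindromic variants are resolved by
allele frequency only when both studies are informative (|eaf − 0.5| >
0.08), otherwise dropped. Variants present in fewer than two studies are
excluded unless passthrough is requested. Lead variants: greedy smallest-p
first with a ±500 kb exclusion window per chromosome. Replication: p <
0.05/n_leads with concordant direction.

**Liability conversion.** The implemented formula is
h²ₗ = h²·[K(1−K)/z²]·[K(1−K)/(P(1−P))], z = φ(Φ⁻¹(K)). Note that evaluating
it at K = 0.015, P = 0.018, h² = 0.0055 gives ≈ 0.047; the conversion factor
K(1−K)/z² exceeds 1 for every K (its minimum is π/2 at K = 0.5), so no
K makes the factor unity. The function is a faithful implementation of the
formula as stated; no published value is asserted against it.

## Natural-effects mediation (`mediate`)

Ratio-of-mediator-probability weighting: fit logistic M ~ factor(X) + C;
expand each subject over hypothetical exposure levels x′; weight by
P(M = m_obs | x′, C)/P(M = m_obs | x_obs, C); fit logistic Y ~ factor(x_obs)
+ factor(x′) + C on the expanded weighted data. The coefficient on the
observed-exposure factor is the natural direct effect, on the hypothetical
factor the natural indirect effect; their sum is the total effect by
construction (exact additivity on the log-odds scale). No exposure-mediator
interaction term is included. Inference: subject-level bootstrap (default
1,000 replicates), se = sd of replicates, Wald p against the normal.
Proportion mediated is computed on the log-OR scale — the scale on which the
decomposition is additive. E-values use E = RR + √(RR(RR−1)) with the OR
standing in for the RR (rare-outcome approximation); protective ORs are
inverted first.

## PWAS (`pwas`)

Preprocessing order is fixed: drop proteins with missingness strictly above
20%, mean-impute, rank-based inverse-normal transform with the Blom 3/8
offset and average ranks for ties, then standardize. Constant columns are
dropped (standardization undefined). Per-protein logistic models share the
scan engine; Bonferroni at 0.05/m and BH q over the m tested proteins.
Pathway enrichment is the one-sided hypergeometric (enrichment direction,
the web-tool convention), two-sided Fisher behind a flag, BH over pathways.

## Selection and prediction (`select_predict`)

The L1 solver is IRLS + cyclic coordinate descent with an active-set
strategy (the glmnet algorithm), compiled with numba; objective tolerance
10⁻⁷. Per-feature penalty factors let demographics stay unpenalized while
proteins are shrunk — the reason a bespoke solver is used at all.
Cross-validation: 100 log-spaced penalties in [10⁻⁶, 0.07], seeded fold
labels shared across the grid, held-out binomial deviance, lambda.1se =
largest penalty within one standard error of the minimum. Stability
selection re-uses the scalar lambda.1se in 100 balanced subsamples (all
cases + an equal number of controls without replacement); features with
selection frequency ≥ 0.5 are kept.

A caveat verified against R glmnet: in a mixed signal + noise configuration,
a penalty tuned on the full (imbalanced, larger) training set is relatively
weak inside balanced subsamples, and 1–5% of pure-noise features can acquire
stable spurious correlations with the fixed case set and pass the 0.5
threshold. This is a property of the protocol, not of this implementation;
under a global null the CV curve is minimized at the top of the grid and
nothing is selected.

Refits: four nested logistic models (demographics; proteins; proteins +
demographics; haplotype + proteins + demographics), with backward
stepwise-AIC elimination over proteins only — drop the protein whose removal
lowers AIC most, ties broken alphabetically, stop when no removal improves.
Evaluation: ROC AUC as the rank statistic (ties 1/2), PR AUC by step
interpolation (average precision), paired DeLong tests via placement-value
covariances. The 80/20 split is simple random, non-stratified.

## Mendelian randomization (`mrlink`)

Clumping: greedy by p; a significant variant within ±250 kb of any retained
index is dropped when r² ≥ 0.2 (r² from a genotype reference panel). A
strict r² < 0.001 mode reproduces the sensitivity re-analysis behaviour.
Instrument filters: cis within ±1 Mb of the gene (inclusive), F = β²/se² ≥
10, associated with < 5 proteins. Estimators on ratio statistics with
first-order delta-method standard errors (exposure error ignored, justified
by the F ≥ 10 screen): Wald ratio (single instrument), fixed-effect IVW with
multiplicative over-dispersion of the se when Q/df > 1 (conservative under
incidental heterogeneity; switchable), weighted median with a 500-draw
seeded parametric bootstrap se, bivariate-normal maximum likelihood (BFGS,
observed-information se), and MR-Egger weighted by 1/se²_out after orienting
exposure effects positive, with the intercept as the directional-pleiotropy
test. Panel: BH q over the primary estimator across testable proteins;
sensitivity and replication re-tests restricted to q-significant proteins,
replication requiring p < 0.05 with concordant direction.

## Colocalization and triangulation (`colocdrug`)

Wakefield log-ABF per variant: ½log(se²/(se²+W²)) + z²W²/(2(se²+W²)), prior
effect sd W = 0.2 for binary-trait log-ORs and 0.15 per SD for protein
traits. Five-hypothesis sums with per-variant priors p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵, evaluated in log-sum-exp arithmetic (H3 uses a stable
log-difference of the product-sum and the diagonal). Category thresholds
default to 0.8 (colocalized) and 0.5 (suggestive); a strict 0.9 mode is
available — both thresholds appear in the source literature and neither is
privileged. The triangulation gate requires PWAS p < 0.05 and MR q < 0.05
with concordant direction; PWAS evidence tiers are bonferroni / fdr /
nominal / none; proteins missing from the user-supplied druggability tier
table are labelled "Not classified".

## Problem sizes in the checks

The property suites run at desk scale, chosen to keep the full suite in the
minutes range while staying in the asymptotic regime of each method: scan
calibration uses 10,000 null variants at n = 5,000; stability selection uses
n = 4,000 cohorts (~400 cases, mirroring the case count of the proteomic
analysis) with 100 proteins; mediation coverage uses 200 replicates of
n = 2,000 with 200 bootstrap draws, the estimand evaluated once at
n = 400,000; MR properties use instrument-level simulation (8–10 instruments,
100–500 replicates); colocalization uses 200-variant regions.

## Known limitations

- Logistic (not mixed-model) association tests; no relatedness, no
  X-chromosome model, no imputation-quality dimension.
- The mediation estimator assumes no unmeasured confounding of any of the
  three edges and no exposure-induced mediator-outcome confounders; E-values
  quantify, not remove, sensitivity to the first assumption.
- Single-causal-variant colocalization only.
- The generator's proteins are conditionally Gaussian given genotype; heavy
  tails, batch effects and detection limits of real proximity-extension
  assays are out of scope.
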