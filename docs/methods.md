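# Methods

This note documents the model, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Discretization

Continuous biomarkers are cut at the empirical 10th/30th/70th/90th
percentiles of each sex's observed values (linear-interpolation
percentile definition), giving five ordinal levels with nominal
10/20/40/20/10% occupancy — asymmetric on purpose, to retain resolution
in the clinically informative tails. Values exactly equal to a cut point
fall in the *lower* bin (right-closed lower bins): deterministic, and on
heavily tied data it keeps bin occupancy at or below nominal rather than
above. Thresholds are fitted on observed values only; missing stays
missing. Blood pressure bypasses quantile binning and uses the 2017
ACC/AHA categories (normal: SBP < 120 and DBP < 80; elevated:
120 ≤ SBP ≤ 129 and DBP < 80; hypertensive: SBP ≥ 130 or DBP ≥ 80). The
choice of guideline (ACC/AHA rather than ESC) is a design decision; the
cut-offs are configurable.

## Profile model and inference

The model is a multinomial mixed-membership model over (biomarker, bin)
tokens — one token per observed participant-biomarker cell. Conditioning
on observed tokens only *is* the missing-data treatment; it is valid
under missingness that is ignorable given the observed data (the
generator uses MCAR per feature; see Limitations). Hyperparameters
default to symmetric α = 1/K on loadings and β_h = 0.1 on the vocabulary
— weakly informative standard choices, both overridable.

Inference is collapsed Gibbs sampling (numba-compiled inner loop; all
randomness flows through one numpy generator, so a chain is bit-for-bit
reproducible from its seed). Defaults: 500 burn-in sweeps, then 100
retained samples at thinning 5; chain c is seeded base_seed + c.
Posterior samples use the Rao-Blackwellized estimates
φ_kv = (n_kv + β_h)/(n_k + Vβ_h) and θ_dk = (n_dk + α)/(n_d + Kα); a
participant with no observed biomarkers gets the prior mean (uniform
1/K). The collapsed log-likelihood is traced every sweep.

**Model selection.** K is chosen by document completion on a
train:validation split of participants, literally 1:2 (train = 1/3;
`train_fraction` is a config switch since the opposite reading is also
defensible). For each validation participant the even-indexed half of
their tokens (in participant-then-feature order, hence deterministic) is
folded in against the training φ to estimate θ, and the odd-indexed half
is scored as mean log Σ_k θ_k φ_kv. Participants with fewer than two
usable tokens are excluded and counted; validation tokens absent from the
training vocabulary are dropped and counted. Ties in the score curve
break toward smaller K (parsimony).

**Convergence.** For each participant the entropy −Σ_k θ_k log θ_k of
every retained loading sample forms one sequence per chain; the classic
between/within-chain variance ratio folds into an R-hat per participant.
The ensemble passes when ≥ 99% of participants have R-hat < 1.1. (With a
single summary per chain the within-chain variance would be undefined,
so the statistic is computed on per-sample entropies.)

## Chain alignment and robustness

Chains recover profiles up to label switching. Each chain's
posterior-mean φ is matched to the reference chain (chain 0) by the
minimum-cost bijection — balanced optimal transport with uniform
marginals, solved as linear assignment — under squared Hellinger
distance, which is bounded, symmetric and well-suited to probability
rows. Relabeling touches labels only; sample content is invariant.
Pooled statistics (mean and equal-tailed 95% credible interval per
(profile, vocabulary) cell) are computed over all relabeled φ samples.

Identifiability filtering treats each chain's posterior-mean profile
vectors as labeled points and computes the standard Euclidean silhouette;
a profile is kept iff its mean silhouette is ≥ 0.1 (configurable). A
profile replicated bit-for-bit across chains is a zero-width cluster and
scores 1 by convention. K = 1 leaves the silhouette undefined; the single
profile is retained with a warning.

## Association and subtype classification

Loadings are rank-transformed — fractional ranks (average rank for ties)
mapped to (0,1) by (r − 0.5)/n, optionally pushed through the
standard-normal quantile function (RINT) — making every p-value invariant
under monotone re-scoring of loadings. Each profile's transformed loading
is regressed by OLS on all predictors jointly (complete-case rows;
dummy-coded categoricals; rank-deficient designs rejected naming the
collinear columns). Bonferroni correction uses the family
profiles × predictors within the analysis block, configurable via
`family_size`.

A profile is a candidate CKM subtype iff its kidney-disease, T2DM and CVD
coefficients are all positive and all Bonferroni-significant;
all-negative-significant is protective; anything else is neither. Note
that loadings are compositional (rows sum to 1), so a genuinely null
profile can acquire negative associations when strongly positive profiles
exist — an honest property of simplex-valued scores, visible occasionally
in the synthetic reports.

Prevalence counts participants whose single-profile loading (per subtype)
or summed candidate loading (overall) meets a threshold, default 50%,
with a sensitivity sweep over (0.5, 0.4, 0.3); overall prevalence is
monotone nonincreasing in the threshold by construction.

## Genetic association

The GWAS response is the rank-inverse-normal transform of the
posterior-mean loading (raw-scale option retained): RINT protects OLS
calibration for the skewed, bounded loadings. Per platform, each
variant's additive dosage is tested by OLS with covariates — two models:
demographics (age, sex, smoking) and demographics + anthropometrics
(BMI, waist-hip ratio, weight). The implementation residualizes the
trait and all dosages against the covariates (Frisch–Waugh–Lovell),
reproducing per-variant full OLS exactly while vectorizing over
variants; monomorphic variants are excluded and counted. Platforms are
combined by fixed-effect inverse-variance weighting
(β = Σwβ/Σw, SE = (Σw)^(−1/2), w = 1/SE²) — the standard estimator for a
batch-split single cohort. Genomic inflation is
λ_GC = median(χ²)/0.4549364. Genome-wide significance is 1·10⁻⁸.

Lead variants come from greedy clumping: repeatedly take the smallest-p
unclaimed significant variant and claim all variants within 500 kb at
sample r² ≥ 0.1 (conventional defaults, configurable). PRS weights are
the meta-analysis betas of the leads; scores are standardized weighted
dosage sums and validated by logistic regression of each disease on
score + covariates (a linear-probability OLS option exists). Leads
absent from the validation genotypes are dropped with a warning.

## Synthetic cohort generator

The generator is the package's study bench; its defaults define the
conditions the tests run under.

- **Profiles.** K_true profiles; each profile's per-feature level
  distribution is Dirichlet(0.2) — "sharp" profiles that put most mass on
  one or two levels, matching the strongly structured profile bars the
  analysis is designed to find. The recorded `true_phi` is the induced
  joint over (feature, level) with a uniform feature marginal.
- **Loadings.** θ_i ~ Dirichlet(α_gen · exp(Σ_j γ_jk g_ij)), default
  α_gen = 0.3 (participants dominated by one or two profiles). The
  multiplicative dosage tilt keeps θ on the simplex and makes
  dosage → loading monotone, hence recoverable by an additive-model GWAS.
- **Biomarkers.** One level per (participant, feature) from the
  θ-mixture; continuous values are produced by placing the level
  uniformly inside its quantile band and mapping through a Gaussian
  marginal, so the discretization stage approximately inverts the
  generator.
- **Missingness.** MCAR per feature (e.g. 0.655 emulates an assay
  observed for ~34.5% of participants). MNAR is out of scope; the real
  missingness mechanism of biobank assays is not claimed to be MCAR.
- **Demographics** are drawn from fixed distributions matching a
  mid-aged population cohort (age ~ N(47, 13), ~50% female, smoking
  never/ex/current ≈ 46/34.5/19.5%), independent of profiles by default
  so type-I-error tests run under a true null.
- **Diseases.** Bernoulli with logit = baseline + w·θ — the weakest
  structure that makes the sign-based subtype rule recoverable.
- **Genotypes.** Biallelic dosages with MAF uniform in (0.05, 0.5),
  arranged in LD blocks (default size 5): within a block the two
  haplotypes reuse a shared latent uniform with probability
  `ld_strength` = 0.8, giving positive within-block r² and independent
  blocks; blocks are laid out across chromosomes. Platform labels are
  multinomial with fractions (0.12, 0.45, 0.43), emulating a three-chip
  cohort split of roughly 6k/24k/23k.
- **Constellation design.** `generate_constellation_cohort` builds the
  designed two-profile cohort in which one variant (γ = 0.7 per allele)
  shifts all 40 features' level distributions slightly
  (±(0.03, 0.05, 0, 0.05, 0.03) around the nominal occupancy): the
  variant's signal concentrates in the profile loading but stays diluted
  in every single (feature, level) indicator.

What the generator does *not* emulate: realistic biomarker marginal
shapes, medication effects, relatedness/family structure, population
stratification, MNAR missingness, longitudinal drift. Passing tests
demonstrate that the chain recovers the structure it assumes — not that
real biobank data satisfies those assumptions.

## Problem sizes and numerical choices

The default verification sizes are desk-scale: profile recovery uses
n = 3,000 participants × 20 features, K_true = 5, four chains of
500 + 500 sweeps; model selection runs 20 seeded replicates over
K ∈ {2..8} with a lighter schedule (150 burn-in, 10 samples at thinning
2); association calibration uses 1,000 null replicates; GWAS calibration
m = 20,000 null variants and 40 power replicates at n = 5,000; PRS
validation n = 10,000. The full suite runs in about a minute on one CPU.

Other numerics: Dirichlet draws via normalized gammas with a 1e-300
floor; token probabilities floored at 1e-300 before logs; credible
intervals are equal-tailed sample percentiles; the assignment solver's
fixed scan order makes tie-breaks deterministic; clumping is
deterministic given its inputs.

## Known limitations

- The profile model is the standard collapsed multinomial
  mixed-membership family; richer "hidden-unit" architectures with
  non-multinomial emissions are out of scope.
- Silhouette filtering operates on posterior-mean profile vectors, not on
  individual samples; a profile that is bimodal *within* a chain can
  evade it (the entropy R-hat usually catches this case instead).
- The GWAS is plain OLS per variant: no mixed models, kinship, or
  imputation — synthetic cohorts are unrelated and fully genotyped by
  construction.
- Logistic PRS validation reports Wald p-values; with very rare outcomes
  a score test would be better calibrated.
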