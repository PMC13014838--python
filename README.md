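# ckm-topics

Mixed-membership ("topic") modelling of clinical blood/urine biomarker
panels for discovering candidate **cardiovascular-kidney-metabolic (CKM)
syndrome subtypes**, with the full downstream chain: covariate/disease
association, subtype classification, genome-wide association of the
profile loadings, fixed-effect meta-analysis across genotyping platforms,
lead-variant clumping, and polygenic-risk-score (PRS) validation in an
independent cohort.

The package is aimed at biostatisticians and genetic epidemiologists who
want to run — or stress-test — this kind of multi-biomarker subtype
analysis without access-restricted biobank data: a first-class synthetic
cohort generator emulates the relevant statistical structure (discretized
biomarkers driven by latent profiles, block-missing assays, diseases
logistic in the loadings, variants with additive effects on loadings,
three genotyping batches) and records complete ground truth, so every
stage is testable end to end.

## The model

Continuous biomarkers are discretized into five sex-stratified percentile
bins (cut points at the 10th/30th/70th/90th empirical percentiles; blood
pressure instead uses the 2017 ACC/AHA normal/elevated/hypertensive
categories). Each participant *d*'s observed bins become tokens over a
vocabulary of (biomarker, bin) pairs, modeled as a mixture of K latent
profiles:

- φ<sub>k</sub> — profile k's distribution over (biomarker, bin) pairs,
- θ<sub>d</sub> — participant d's profile loadings (a point on the
  K-simplex, readable as 0–100% profile scores),

with symmetric Dirichlet priors α on θ and β<sub>h</sub> on φ. Inference
is collapsed Gibbs sampling over token–profile assignments:

P(z = k | rest) ∝ (n<sub>dk</sub> + α) · (n<sub>kv</sub> + β<sub>h</sub>) / (n<sub>k</sub> + V·β<sub>h</sub>)

Missing biomarkers contribute no token, which is exactly posterior
conditioning on the observed data — no imputation. K is chosen by
held-out document-completion likelihood on a 1:2 train:validation split;
several independent chains are matched by optimal transport (minimum-cost
bijection under squared Hellinger distance between φ rows), profiles that
fail to replicate across chains are dropped by silhouette score, and the
surviving samples are pooled into 95% credible intervals.

Downstream, rank-transformed loadings are regressed on demographics,
anthropometrics and self-reported disease (OLS, Bonferroni-corrected
t-tests). A profile simultaneously, significantly and *positively*
associated with kidney disease, type-2 diabetes and cardiovascular
disease is a **candidate CKM subtype**; all-negative gives a *protective*
profile. Per genotyping platform, each variant's additive dosage is
tested against the rank-inverse-normal loading (two covariate models);
platforms are combined by inverse-variance-weighted meta-analysis;
significant variants (p < 1·10⁻⁸) are reduced to leads by greedy r²/window
clumping; and lead effect sizes define per-subtype PRS validated by
logistic regression in a disjoint cohort.

## Worked example

```python
import numpy as np
from ckm_topics import (DiseaseSpec, GenConfig, generate_cohort,
                        associate, classify_subtypes, prevalence)
from ckm_topics.alignment import align_ensemble, best_matched_tv, silhouette_filter
from ckm_topics.topic_model import expand_phi, fit_chain, tokenize

# 5 latent profiles; profiles 0,1 raise all three CKM diseases, 2,3 lower them
w = np.array([4.0, 4.0, -4.0, -4.0, 0.0])
cfg = GenConfig(
    n_participants=3000, n_features=20, K_true=5,
    topic_sharpness=0.2, alpha_gen=0.3,
    disease_specs=[DiseaseSpec(d, -2.0, w)
                   for d in ("kidney_disease", "t2dm", "cvd")],
    seed=1,
)
cohort, binned, truth = generate_cohort(cfg)

tokens = tokenize(binned)
chains = [fit_chain(tokens, K=5, n_burn=500, n_samples=100, thin=5, seed=c)
          for c in range(4)]
ens = silhouette_filter(align_ensemble(chains), threshold=0.1)
phi = expand_phi(ens.pooled_phi_mean, tokens.vocabulary, binned.feature_names, 5)
tv, _ = best_matched_tv(truth.true_phi, phi)
print(f"robust topics: {len(ens.robust_topics)} / 5")
print(f"mean TV(fitted, true): {tv:.3f}")

theta = np.mean([c.theta_mean for c in ens.chains], axis=0)
tab = associate(theta, cohort[["kidney_disease", "t2dm", "cvd", "age", "sex"]])
calls = classify_subtypes(tab)
print(calls.to_string(index=False))

candidates = calls.loc[calls.call == "candidate_CKM", "topic"].tolist()
rep = prevalence(theta, candidates, threshold=0.5, sweep=(0.5, 0.4, 0.3))
print(rep.sensitivity[["threshold", "overall_cases", "overall_fraction"]]
      .to_string(index=False))
```

Output (~12 s on one CPU):

```
robust topics: 5 / 5
mean TV(fitted, true): 0.041
 topic          call
     0 candidate_CKM
     1       neither
     2 candidate_CKM
     3    protective
     4    protective
 threshold  overall_cases  overall_fraction
       0.5           1101             0.367
       0.4           1311             0.437
       0.3           1560             0.520
```

All five generated profiles replicate across the four chains; the pooled
profile tables sit within 0.041 total-variation distance of the
generating truth; the two planted risk profiles are recovered as
candidate CKM subtypes and the two planted protective ones as protective
(fitted topic indices are arbitrary up to label switching); and subtype
prevalence grows monotonically as the loading threshold is relaxed from
50% to 30%.

## Command-line pipeline

The same chain runs stage-by-stage from a YAML config, writing plain-text
artifacts and a reproducibility manifest per stage:

```bash
ckm-topics all --config config.yaml --out run1/       # or one stage at a time:
ckm-topics simulate   --config config.yaml --out run1/
ckm-topics discretize --config config.yaml --out run1/
ckm-topics fit        --config config.yaml --out run1/ --seed 7
...
cat run1/report.txt
```

Stages: `simulate → discretize → fit → align → associate → gwas → prs →
report`. Defaults mirror the analysis settings (8 chains, 500 burn-in +
100 thinned samples, silhouette threshold 0.1, loading threshold 0.5 with
a 0.5/0.4/0.3 sensitivity sweep, genome-wide significance 1·10⁻⁸,
clumping at r² ≥ 0.1 within 500 kb).

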