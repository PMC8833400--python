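# radsurv

Batch-effect harmonization of radiomic feature tables, unsupervised binary
imaging phenotypes, and Cox-model evaluation of the phenotype's added
prognostic value — the complete analysis pipeline for studies that ask
whether a CT-derived tumor phenotype improves overall-survival prediction
over clinical predictors, exercised end-to-end on a built-in synthetic
cohort generator.

## The problem

Radiomic features (shape, intensity, texture descriptors computed from a
segmented tumor on CT) carry systematic, non-biological variation from
acquisition factors: whether intravenous contrast was used, and which
scanner vendor produced the image. Left uncorrected, these *batch effects*
swamp the biological signal that unsupervised phenotyping is after. This
package implements:

1. **Nested ComBat harmonization.** ComBat models feature *g* of a patient
   in batch *i* as
   `x_ig = α_g + X β_g + γ_ig + δ_ig ε_ig`,
   estimates the additive (γ) and multiplicative (δ) batch effects by
   empirical Bayes — per-batch estimates shrunk toward moment-matched
   normal / inverse-gamma priors — and removes them:
   `x*_ig = σ_g (z_ig − γ*_ig)/δ*_ig + α_g + X β_g`.
   With several batch variables (here: contrast and vendor), the nested
   loop harmonizes the running matrix by every remaining candidate,
   counts features still differing across batch levels (pairwise
   two-sample Kolmogorov–Smirnov tests at α = 0.05), adopts the candidate
   leaving the fewest flags, and repeats until no variables remain.
   Output is numerically exchangeable with the reference genomics
   implementations (verified against `sva::ComBat` to 1e-15 in the tests).

2. **Binary imaging phenotype.** PCA keeps the leading components
   explaining 85% of the variance; consensus clustering over patient
   subsamples (PAC criterion) selects the cluster count; complete-linkage
   hierarchical clustering of the PC scores yields labels; the cluster
   with the higher observed death fraction is the "high-risk" phenotype.

3. **Survival evaluation.** Cox proportional-hazards models (Efron ties,
   score equation verified to |grad| < 1e-6), Harrell's concordance index
   (C-score), bootstrap-t confidence intervals (B patient-level resamples,
   models refit per resample), likelihood ratio tests against the clinical
   baseline (ECOG + age), and Kaplan–Meier curves.

Because real cohorts of this kind are restricted, the `simulate` module
generates cohorts with the same statistical structure: 110 patients,
107 features, the study's batch prevalences, ~51% death events with
median overall survival 30.6 months, a latent two-group phenotype
(log HR = log 2) carried by 20 informative features, and per-batch
location/scale distortions following the ComBat generative model.

## Worked example

```python
import radsurv as rs

cfg = rs.PipelineConfig(
    simulation=rs.SimulationConfig(seed=7),
    evaluation=rs.EvaluationConfig(n_bootstrap=1000, seed=7),
    seed=7,
)
res = rs.run_pipeline(cfg)
print(res.summary())
```

prints

```
Radiomic phenotype survival analysis
====================================================================
patients: 110   events: 51 (46.4%)
harmonization order: vendor -> contrast
KS-flagged features pre -> post: contrast: 75 -> 0, vendor: 85 -> 5
retained PCs (>= 85% variance): 44
cluster count k: 2

Univariate C-scores
--------------------------------------------------------------------
race                         C = 0.58 (0.53, 0.64)
bmi                          C = 0.57 (0.49, 0.67)
ecog                         C = 0.57 (0.50, 0.64)
Phenotype (ComBat)           C = 0.55 (0.48, 0.62)
sex                          C = 0.54 (0.48, 0.61)
age                          C = 0.53 (0.48, 0.61)
Phenotype (non-ComBat)       C = 0.51 (0.47, 0.58)
pack_years                   C = 0.47 (0.42, 0.63)

Multivariate models (LRT vs ECOG + Age baseline)
--------------------------------------------------------------------
ECOG + Age (Baseline)                C = 0.58 (0.52, 0.67)  --
Phenotype (ComBat) + ECOG + Age      C = 0.58 (0.53, 0.70)  p = 0.036
Phenotype (non-ComBat) + ECOG + Age  C = 0.58 (0.53, 0.68)  p = 0.373
7 PCs + ECOG + Age                   C = 0.71 (0.66, 0.82)  p = 0.000
```

Reading this: harmonization collapsed the count of batch-flagged features
from 75/85 (contrast/vendor) to 0/5; consensus clustering found two stable
patient groups on the harmonized features; the phenotype built from
*harmonized* features adds significant prognostic value over the ECOG+age
baseline (LRT p = 0.036), while the phenotype built from unharmonized
features does not (p = 0.373) — the package's core comparison. C-scores
are in-sample Harrell concordances with bootstrap-t 95% CIs; 0.5 is
chance.

`RadiomicSurvivalModel.from_csv(dir)` runs the same analysis on your own
four CSV tables (`features.csv`, `batches.csv`, `clinical.csv`,
`survival.csv`, all keyed by a `patient_id` column), and every stage is
callable on its own (`nested_combat`, `PhenotypeModel`, `run_univariate`,
`run_multivariate`, ...). A CLI mirrors the stages:

```sh
radsurv simulate --seed 7 --outdir cohort/
radsurv harmonize --features cohort/features.csv --batches cohort/batches.csv --out harm/
radsurv run --config config.yaml --outdir out/
```

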