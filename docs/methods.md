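# Methods

This note records the statistical model, the defaults and the design
choices behind `radsurv`, and what the synthetic-cohort tests do and do
not establish about real data.

## ComBat location/scale model

Each feature *g* of patient *j* in batch *i* is modelled as

    x_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg,    ε ~ N(0, σ_g²)

Fitting follows the reference genomics implementations step for step, so
output is exchangeable with them:

- **Standardization.** α̂_g and β̂_g come from least squares on the design
  [batch indicators | protected covariates]; the grand mean is the
  batch-size-weighted combination of batch intercepts; the pooled variance
  σ̂_g² is the mean squared residual with denominator *n* (not n−1).
  z = (x − α̂ − Xβ̂)/σ̂.
- **Empirical Bayes.** Raw per-batch locations γ̂_ig (batch means of z) and
  scales δ̂_ig² (batch sample variances, denominator n_i−1) are shrunk
  toward priors γ ~ N(γ̄_i, τ_i²) and δ² ~ InvGamma(λ_i, θ_i) whose
  hyperparameters are moment-matched across features within each batch.
  The posterior-mean updates are iterated to a maximum *relative* change
  below `eb_tol` (default 1e-6; the reference implementation fixes 1e-4).
  The relative-change rule is deliberate: it is what the reference code
  uses, and equivalence with it is part of the test suite (elementwise
  agreement with `sva::ComBat` to 1e-15 on a 110×107 cohort).
- **Adjustment.** x* = σ̂ (z − γ*)/δ* + α̂ + Xβ̂. Protected covariate
  effects re-enter unchanged. A batch variable with a single observed
  level is a no-op by construction (there is no contrast to remove; a
  literal one-batch EB fit would give δ̂ = n/(n−1) ≠ 1 and perturb the
  data for no reason). Zero-variance features pass through untouched.

Constant feature columns are z-scored to all-zero with a warning rather
than dropped, preserving the input column contract. The parametric prior
is the only implemented variant; `prior="nonparametric"` raises.

## Nested harmonization over multiple batch variables

The matrix is z-scored once (sample sd, denominator n−1). At each
iteration every remaining batch variable harmonizes the current matrix
separately; each candidate result is scored by the number of features
whose distributions still differ across batch levels — all unordered
level pairs compared by two-sided two-sample KS tests at α = 0.05, a
feature flagged if any pair rejects, no multiplicity correction — and the
candidate with the fewest flags wins, ties resolved toward the earliest
input column. Exactly one iteration runs per batch variable.

Candidate scoring sums the flag counts over **all** batch variables by
default (`ks_scope="all"`). Scoring each candidate only against its own
variable (`ks_scope="own"`, also available) makes the selection
uninformative when batch assignments are independent: every candidate
scores near the null count for its own variable, and the "ordering by
effect size" the procedure is meant to produce degrades to a coin flip.
Under the default, the variable carrying the distortion is selected first
in essentially every simulated replicate.

KS p-values are asymptotic by default (`ks_mode="exact"` available for
small batches). On null data (no batch effects) the asymptotic
two-sample test is conservative at these sample sizes, so the mean flag
count sits slightly below 107·α.

A residual empirical-Bayes adjustment remains even when no batch effects
exist, because γ* and δ* are estimated from finite batches: at n = 110
with the default batch prevalences (smallest vendor batch ≈ 7 patients) a
single ComBat pass moves each z-scored value by ≈ 0.03 on average, and
the two-pass nested output by ≈ 0.06. This is intrinsic to ComBat (the
reference implementation produces the identical numbers) and vanishes as
batches grow; the test suite pins both the single-pass magnitude and the
monotone decrease toward zero as planted effects shrink.

## Phenotype derivation

- PCA on the (already z-scored, harmonized) features, centered, full SVD;
  the retained dimension *m* is the smallest with cumulative explained
  variance ≥ 85%. Component signs are fixed by making each component's
  largest-magnitude loading positive, so results are reproducible across
  runs and libraries.
- Consensus clustering: 1000 subsamples of 80% of patients without
  replacement, complete-linkage (maximum distance) hierarchical
  clustering on Euclidean distances, cut at each k in [2, 6];
  consensus(i,j) = co-clustered / co-sampled; PAC = fraction of defined
  off-diagonal consensus entries strictly inside (0.1, 0.9); the k with
  minimal PAC wins, ties to the smaller k. Pairs never co-sampled are
  excluded from PAC with a warning.
- Labels come from the complete-linkage dendrogram cut at the selected k.
  The *risk* phenotype is binary by contract: when consensus prefers
  k ≠ 2 (typical for unharmonized, batch-distorted features, which have
  no stable cluster structure), the 2-cluster cut still defines the risk
  groups and the audit trail records the disagreement
  (`binary_cut_forced`).
- Risk orientation is outcome-aware by default: the cluster with the
  higher observed death fraction is "high", ties broken toward the
  shorter median observed time. An outcome-blind alternative (orient by
  first-PC mean) is available via `outcome_aware=False`.
- Phenotype–covariate associations: Kruskal–Wallis for age, BMI,
  pack-years; chi-squared contingency tests without continuity correction
  for sex, race, ECOG and the event of death; degenerate tables are
  reported as non-significant with a warning.

## Survival evaluation

- Cox fits use lifelines (Efron tie handling, no penalty). The Efron
  score equation is re-evaluated here at the estimate and polished by
  Newton steps with monotone step-halving when needed, so every returned
  fit satisfies max |gradient| < 1e-6.
- Harrell's C counts pairs whose shorter observed time is an event; pairs
  tied in time with both events are unusable; an event tied with a
  censoring is usable (the event subject should carry the higher risk);
  tied scores contribute 1/2. The implementation is exact against
  exhaustive pair enumeration.
- Bootstrap-t CIs: B patient-level resamples with replacement; the Cox
  model is refit per resample while phenotype labels stay fixed as
  derived on the full cohort (the resampling-validation design of the
  analysis; a fully nested re-derivation is available via
  `refit_phenotype=True` at proportionally higher cost). CI = mean ±
  t_{(1+level)/2, B−1} × sd of replicate statistics. Replicates that fail
  to fit are dropped and counted; more than 10% failures is an error.
  The production default is B = 50 000; pipelines and tests run B =
  500–2000, which changes the CI half-widths by well under the reporting
  precision.
- Indicator encoding uses the most frequent level as reference and pools
  levels with fewer than 5 patients into one bucket: singleton indicator
  levels produce monotone-likelihood separation under resampling.
  Indicator columns constant within a bootstrap resample (level not
  drawn) are dropped from that replicate's refit. ECOG enters models as
  ordinal 0/1/2; patients with unknown ECOG are excluded complete-case
  from every model in the multivariate comparison, so the LRTs compare
  identical subjects.
- The multivariate comparison fits: baseline (ECOG + age), baseline +
  each phenotype, and baseline + the PCs whose Wald tests in the joint
  Cox fit of all retained PCs reject HR = 1 at 0.05 (none passing yields
  a baseline-equivalent entry with a note). LRT statistics are
  2(ℓ_full − ℓ_nested) against χ² with the parameter-count difference.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes; its
defaults are the study conditions and are not tuned per-test.

| parameter | default | meaning |
|---|---|---|
| n_patients / n_features | 110 / 107 | cohort and feature-table size |
| batch prevalences | contrast 74.5/25.5; vendor 60.9/32.7/6.4 (%) | acquisition mix |
| gamma_sd | 1.0 | sd of additive per-batch feature shifts (z-units) |
| delta_range | (0.5, 2.0) | support of multiplicative per-batch scales |
| phenotype_separation | 2.0 | mean shift on informative features (z-units) |
| n_informative | 20 | features carrying the phenotype |
| log_hr_phenotype | log 2 | planted hazard ratio of the latent phenotype |
| log_hr_age / log_hr_ecog | 0.2 / 0.3 | clinical log HRs (age per IQR; ECOG per step) |
| baseline_median_months | 30.6 | median OS at the reference covariates |
| target_event_fraction | 0.509 | expected death fraction |

Features are iid N(0,1) per patient before the phenotype shift and the
batch distortions x' = xδ + γ (γ ~ N(0, gamma_sd²), δ ~ U(delta_range),
drawn per batch level and feature; per-variable overrides accepted).
Clinical covariates are drawn from the cohort's marginals: age truncated
normal matched to median 66, IQR (60, 71); BMI analogous; pack-years
lognormal (median 35) with a 5.5% never-smoker mass at zero; ECOG
multinomial (45.5/43.6/9.1/1.8% unknown); sex and race per the cohort
table. Survival is Weibull proportional hazards (exponential by default)
with linear predictor over phenotype, standardized age and ECOG, the
baseline scale set so the reference patient's median survival equals
30.6 months. Censoring is administrative — entry uniform over an accrual
window, so censoring times are uniform on (0.25·H, H) — with the horizon
H solved by quadrature + Brent root-finding so the expected event
fraction hits the target. Batch assignment is independent of the
phenotype by default; `batch_phenotype_confounding` tilts the first
level's log-odds for high-risk patients when confounded regimes are
needed.

What the generator does **not** emulate: the correlation structure of
real radiomic features (real feature sets are highly redundant, so a
handful of PCs can reach 85% variance; with iid features the same
threshold retains ~45 of 107 components), non-proportional hazards,
informative censoring, and any dependence of image quality on outcome.
Consequently, passing tests demonstrate that the pipeline recovers
planted structure under its own model assumptions — not that it would
find a phenotype in any particular real cohort.

## Problem sizes in the shipped tests

Replicate counts were fixed in advance to keep the default suite and the
acceptance script in the minutes range on one CPU: 100-seed loops for
batch-effect removal, nested ordering, phenotype recovery and the
headline comparison; 200 replications for LRT null calibration and
bootstrap coverage; 1000 random instances for the concordance oracle;
B = 500–2000 bootstrap replicates (50 000 documented as the production
default). The 100-seed headline loop fixes k = 2 (the consensus result
on harmonized features, exercised separately) and compares point
C-scores; bootstrap CIs are audited on one seed.

## Known limitations

- Only the parametric EB prior; no reference-batch, longitudinal or
  GAM-based ComBat variants.
- The KS flag count uses no multiplicity correction (by design — it is a
  relative ranking criterion, not an inference).
- In-sample C-scores without cross-validation mirror the analysis design
  this package implements; they are optimistic as absolute performance
  estimates, and the LRT against the baseline is the guarded comparison.
- Complete linkage is discontinuous: near-duplicate inputs can flip
  borderline patients between clusters, so harmonized and unharmonized
  phenotypes agree only approximately even when no batch effects exist.
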