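# Methods

## The model

`psomics` builds **profile scores** (PS) — weighted sums of selected omics
features,

    PS_i = sum_{k=1..K} beta_k * m_ik,

where `m_ik` is the value of feature `k` in sample `i` and `beta_k` a weight
estimated on training data — and validates them against an **ordered**
neuropathology outcome with the proportional-odds (cumulative logit) model

    P(Y_i <= l | x_i) = sigma(theta_l - x_i' beta),   l = 1..L-1,

with strictly increasing thresholds `theta` and slopes `beta` shared across
all cumulative splits.  The sign convention is fixed package-wide: a positive
slope shifts mass toward *higher* (worse) outcome categories, so positive
profile-score weights mean "deleterious".

Model evaluation uses the **partial McFadden R²**

    R²_partial = 1 - llf(PS terms + covariates) / llf(covariates only),

with both models fitted on the same (test) samples, so the statistic isolates
the PS contribution beyond age at death, sex, race, educational attainment,
neighborhood deprivation (ADI) and postmortem interval (PMI).  Significance
is a likelihood-ratio test of the full against the covariates-only model with
df = the number of PS terms actually entering (1 for single/multi-omics
models, 2 for the joint model, 3 with the interaction).  We count all added
terms in the df; a constant (zero-variance) PS is dropped from the model and
from the df, and if no PS terms remain the result is defined as R² = 0,
p = 1.  PS terms are z-scored before entering so interaction coefficients
are comparable across split seeds.

## Pipeline

One iteration = one seed: (0/1) link layers, impute, z-score by training
statistics, split samples 50/50; (2) estimate weights on the training half
with each method; (3) score the test half; (4) fit single-, multi- and
joint-PS ordinal models on the test half.  Ten seeds by default; aggregation
reports the median partial R², the mean number of selected features K, and
the count of significant iterations.  Feature-stability lists collect
features selected in at least 1/2/3 of the seeds.

### Weight-estimation methods

- **PT (pruning & thresholding).**  Pruning: complete-linkage agglomerative
  clustering of features on the distance 1 − |Pearson ρ|, cut to
  `n_clusters` (default `min(p, 5·n_train)`), keeping each cluster's medoid
  (highest mean |ρ| to co-members; ties broken by feature id).  Absolute
  correlation is used so anti-correlated duplicates merge; a signed-distance
  variant is available.  Thresholding: a per-feature covariate-adjusted
  proportional-odds fit; features with slope Wald p < 0.05 enter the PS with
  the fitted slope as weight — the marginal-effect weighting of the
  polygenic-score tradition.
- **EN (ordinal elastic net).**  Proportional-odds likelihood plus
  `lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2²)` on the feature slopes
  only (thresholds and covariates unpenalized), solved by proximal gradient
  with backtracking and warm starts along a 50-point lambda path spanning
  four decades below the data-derived `lambda_max` (penalty on the
  mean-log-likelihood scale, glmnet-style); lambda chosen by k-fold (default
  5) cross-validated deviance inside the training half.  In high dimension
  EN is applied after pruning (PT+EN), as one would on a 790k-CpG array.
- **BO (component-wise ordinal boosting).**  Start from the closed-form
  null thresholds with zero slopes; each iteration regresses the negative
  loss gradient w.r.t. the linear predictor on every candidate column by
  simple least squares, advances the best-fitting component by `nu = 0.1`
  times its fit, then re-optimizes each threshold with a damped
  one-dimensional Newton step.  Training loss is enforced non-increasing by
  step halving.  Early stopping minimizes deviance on an internal 25%
  validation split.  No post-hoc coefficient rescaling is applied beyond
  input standardization.
- **RF (random-forest importance).**  A regression forest on the integer
  outcome codes (preserving level order and avoiding arbitrary multiclass
  importance aggregation), `mtry = sqrt(p)`, 1000 trees.  Importance is the
  classic out-of-bag permutation measure computed per tree; features with
  VIM > 0 enter the PS with weight VIM × sign(Spearman ρ(feature, outcome)),
  since an unsigned importance cannot encode protective vs deleterious
  direction.  Permutation importances of weak effects converge to their
  expectations only with many trees; analyses that score recovery of weak
  planted effects use 4000 trees, while the pipeline default of 1000 trades
  stability for speed.
- **WA (windowed cross-leverage).**  Features are covered by non-overlapping
  windows (default width 2·n) in their stored order.  Within a window, Z is
  the column-standardized [X_window, y]; with the thin SVD Z = U D V'
  truncated to rank r = min(n−1, w+1), the cross-leverage of feature j is
  the (j, y) entry of the projection V V' onto the top-r right-singular
  subspace.  The q = 5 features with largest |score| per window are selected
  with the score as weight.  A configuration in which the projection is the
  identity (all scores exactly zero) raises an error instead of returning
  arbitrary ties.

### Metabolomics QC

Replicate-level screening mirrors LC-HRMS practice: keep features detected
in **more than** 15% of samples, with median technical CV **below** 30%, and
replicate agreement ρ **above** 0.7.  CV is SD/mean of the non-zero
replicates per sample-feature (at least two required); agreement is the
median of the three pairwise Pearson correlations across samples where both
replicates are non-zero — both choices are robust to non-detected cells,
which the source protocols leave unspecified.  Surviving features are
averaged over non-zero replicates and log2-transformed; all-zero cells
become missing and are later imputed by iterative random-forest regression
(features swept in decreasing-missingness order until the mean absolute
change of imputed cells is below 1e-4 or 10 sweeps).

### Leakage policy

Imputation and standardization statistics are fitted on the training half
and applied to the test half by default (`scope="train-fitted"`); a
`global` scope that fits them on all samples (the ordering some published
pipelines imply) is available but not the default.  Weight estimators
receive only the training partition by interface, and a dedicated test
verifies that corrupting test-half outcomes changes no weight set.

## The synthetic-data generator

Because the target data (brain-bank DNAm + metabolomics with neuropathology
gradings) are access-restricted, the package ships a generator that emulates
their statistical structure:

- **Features.**  Standardized latent features in equicorrelated blocks
  (default block size 10, within-block ρ = 0.3 — the local correlation of
  CpG neighborhoods and co-eluting metabolite features).  Observables are a
  logit-normal transform for DNAm (beta values strictly inside (0,1)) and
  affine log2-scale intensities for metabolites.
- **Outcome.**  A latent liability y* = planted effects + covariate effects
  + standard *logistic* noise, cut at empirical quantiles to hit the target
  class frequencies.  Logistic noise makes the proportional-odds model the
  exact data-generating process, so parameter-recovery tests are sharp;
  quantile thresholds guarantee the class frequencies for any effect
  configuration.
- **Planted effects** have magnitude `effect_sd` with random sign
  (Rademacher): the effects' standard deviation equals `effect_sd` while
  every planted feature is genuinely causal — Gaussian effect draws would
  plant near-zero "causal" features whose recovery is undefined.
- **Covariate and outcome marginals** default to the target study
  population: age ~ N(76.4, 10.0) truncated to [57, 105] years; 54.8% male;
  10.8% Black; education (22.3, 49.7, 28.0)%; ADI ~ N(36.1, 24.0) truncated
  to [1, 94]; PMI lognormal moment-matched to mean 11.6 h, SD 9.6 h, clipped
  to [1.5, 64]; ABC class frequencies (9.6, 17.8, 13.4, 59.2)%; Braak uses
  six levels (stage 0 omitted — unobserved in the target population); CERAD
  (21.7, 1.9, 6.4, 70.1)%.  Covariate effects default to a small non-zero
  vector so covariate adjustment is never vacuous in tests.
- **Replicates.**  The raw-intensity triplicate table applies multiplicative
  lognormal noise of a configurable CV, zeroes a configurable fraction of
  cells ("not detected"), and can deliberately break features against each
  QC rule to give the screen known ground truth.

What the generator does **not** emulate: genomic coordinates and CpG
annotation, m/z–adduct chemistry, batch effects, cell-type composition, or
heavy-tailed intensity distributions.  Passing tests therefore demonstrate
the statistical machinery, not robustness to array- or LC-MS-specific
artifacts, which upstream tooling must handle.

## Problem sizes and numerical choices

Test and validation runs use desk-scale sizes chosen to preserve the n ≪ p
regime of the target study (n ≈ 160 samples vs p = 2000 DNAm + 1000
metabolite features, against the study's 790k + 35k): all pipeline behavior
of interest — selection calibration, shrinkage paths, split-to-split
variability — is present at these sizes.  Absolute R² values at desk scale
are naturally smaller than the published brain-bank values and are not
comparable to them.

- The ordinal likelihood is maximized by L-BFGS with an analytic gradient in
  a reparameterized space (first threshold + log-increments) that enforces
  threshold monotonicity; a ridge `1e-8` on slopes keeps separation finite.
  Standard errors come from the observed information (finite differences of
  the analytic gradient).  Unobserved outcome levels are dropped with
  renumbering before fitting — small test splits can miss a level, and the
  cumulative logit is undefined for empty categories.
- Elastic-net subproblems stop when the max parameter move falls below 1e-7
  (cap 400 iterations); the CV deviance of a fold skips held-out samples
  whose level the fold never saw.
- Splits are plain uniform partitions (no stratification), matching the
  repeated-split protocol; per-component random streams (split, imputation,
  forest, CV folds, boosting validation split) are derived independently
  from the iteration seed, so changing one method never perturbs another's
  randomness.
- Pathway enrichment is an annotation-driven one-sided hypergeometric test
  over user-supplied feature→entity→pathway TSV maps — an engine-agnostic
  stand-in for database-tied engines (probe-bias-corrected gene-set tests,
  adduct-matching metabolite tools), which require external annotation
  databases.  Cross-layer combination is Fisher's method, −2Σln p ~ χ²(2k).
  Raw p-values are reported (with a Benjamini–Hochberg column alongside);
  combined values are comparable only within this generic engine.

## Known limitations

- The cross-leverage definition is pinned to the projection-matrix
  off-diagonal given above; other screening variants exist in the
  literature.
- RF selection uses the permissive VIM > 0 rule; under a global null this
  admits roughly half the features with tiny weights (importances are
  symmetric about zero), so K is large and unstable there — the weights,
  not the membership, carry the information.
- EN at the CV-chosen penalty correctly selects nothing when no feature's
  signal exceeds the extreme-value noise floor (weak effects at n_train ≈ 80
  among thousands of features); this is a property of the estimand, not a
  failure of the solver.
- The joint-model df counts all added PS terms (2, or 3 with interaction);
  sequential per-term tests are not provided.
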