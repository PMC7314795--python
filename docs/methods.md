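# Methods

## The batch-effect model

Radiomic features measured at different centers (scanners, protocols,
reconstruction settings) carry systematic non-biological variation.
`radharmony` models an observed feature value for sample *j* of batch *i*
and feature *g* as

    Y_ijg = alpha_g + X_ij beta_g + sigma_g (gamma_ig + delta_ig eps_ijg)

where `alpha_g` and `sigma_g` are the feature's biological location and
scale, `X beta_g` an optional covariate term, `gamma_ig` an additive batch
shift (expressed in `sigma_g` units), `delta_ig` a multiplicative spread
distortion, and `eps` standard Normal noise.  Harmonization estimates and
removes `gamma` and `delta` while preserving `alpha`, `beta`, `sigma`.

### Estimation (all variants)

1. **Standardize.**  Grand mode fits batch indicators plus covariates by
   OLS; `alpha_g` is the sample-size-weighted mean of the batch intercepts
   and `sigma_g^2` the pooled residual variance with the **1/N** divisor.
   `Z = (Y - alpha - X beta) / sigma`.  Batchwise (reference) mode uses each
   batch's own intercept and scale (ddof = 1), so `Z` has mean 0 and unit
   sample variance inside every batch.
2. **Estimate batch effects.**  `gamma_hat_ig` is the within-batch mean of
   `Z`, `delta2_hat_ig` the within-batch sample variance (ddof = 1).
3. **Shrink (empirical Bayes).**  Per batch, the raw effects are pooled
   across features under a Normal prior on `gamma` and an Inverse-Gamma
   prior on `delta^2`, hyperparameters fitted by the method of moments.
   The *parametric* solver iterates the conditional posterior means to a
   relative tolerance of 1e-4 (max 500 iterations); the *nonparametric*
   solver computes each feature's posterior as the likelihood-weighted
   average of all other features' raw estimates (Monte-Carlo integration in
   log space).  `prior="none"` skips shrinkage entirely — a diagnostic mode
   whose output has an exact closed form (per-batch standardization followed
   by a rescale), used as the oracle in the tests.
4. **Adjust.**  `Y* = (sigma_target / delta*_i)(Z - gamma*_i) + alpha_target
   + X beta`, with the pooled (`combat`, `b-combat`) or the reference
   batch's (`m-combat`, `bm-combat`) location and scale as target.

The grand-mode parametric and nonparametric paths reproduce the R reference
implementation (`sva::ComBat`) to better than 1e-6 (in practice ~1e-13 on
small fixtures); this fixes otherwise-arbitrary conventions, in particular
the **1/N pooled variance together with the ddof = 1 within-batch
`delta^2`**.  One consequence worth knowing: with these mixed divisors a
second grand-mode pass over already-harmonized data contracts it toward the
grand mean by exactly `sqrt((N - I)/N)` — grand-mode harmonization is only
asymptotically idempotent, exactly like the reference implementation.
Reference-mode (batchwise) harmonization uses ddof = 1 consistently and is
exactly idempotent, and it returns the reference batch bit-for-bit when
`prior="none"`.

### Bootstrap variants (B-ComBat, BM-ComBat)

The coefficient estimates are replaced by Monte-Carlo means over `B`
bootstrap refits (default `B = 1000`; the seeded studies in the test-suite
and acceptance script use `B = 40..100` with the Monte-Carlo error checked
separately).  Two resampling schemes are provided:

* `case` (default): resample samples with replacement, stratified within
  batch; degenerate resamples (a batch losing all variance in some feature)
  are redrawn and counted, with an error past 50% redraws.
* `parametric`: draw new data from the fitted Normal location-scale model.

Averaging is performed **in the raw-data frame** — per-batch location
`alpha + sigma gamma*` and scale `sigma delta*` — and converted back to
standardized-scale coefficients.  Averaging the standardized-scale
coefficients directly would mix incommensurate frames (each resample has
its own `sigma_k`) and accumulate Jensen-type ratio biases.  At `B = 1` the
procedure reduces exactly to the single-fit coefficients.

An alternative adjustment that divides the centered raw values by `delta*`
without the `sigma/delta*` rescaling is available behind
`literal_bootstrap_form` / `--bootstrap-form literal`; it changes the
output scale and is off by default because the bootstrap is meant to
stabilize estimation, not to alter the target scale.

### What the bootstrap does and does not improve

Bootstrap refits see a resampling-inflated spread of `gamma_hat` across
features, so each refit shrinks *less*; the averaged coefficients therefore
sit closer to the raw batch effects than the single-fit EB estimates.  Two
consequences, both verified by the seeded studies:

* the harmonized output shows **lower dispersion** (aggregate COV) and
  **smaller residual batch effects** — batch removal is more complete, and
  downstream external-validation performance improves;
* under data generated *exactly* from the Normal model with homogeneous
  batch effects, the single-fit EB estimator is already near-optimal for
  recovering the true coefficients, so the bootstrap variant's
  coefficient-recovery error is not smaller there.  The practical benefit
  of the bootstrap lies in the completeness of removal and in robustness,
  not in truth-recovery under ideal conditions.

## Label discovery

When batch labels cannot be assigned by hand, samples are clustered by
agglomerative hierarchical clustering under Euclidean distance (default
Ward linkage; average/complete available).  Features are z-scored before
distance computation because radiomic features span wildly different
physical units.  The number of clusters is the arg-max of the mean
silhouette width over a candidate range (default 2..10), ties broken toward
smaller k (more samples per batch for the downstream estimation).
`outcome_balance_check` compares per-cluster event rates (two-proportion
z-test for two clusters, chi-square beyond) and warns when clusters may
encode outcome rather than acquisition effects.

## Evaluation battery

* **Per-feature ANOVA** — classic equal-variance one-way F-test across
  batch labels; the headline number is the fraction of features with
  p < 0.01.
* **Aggregate COV** — the sum over features of |SD/mean| x 100.  This is a
  defined, documented statistic of this package (a single dispersion number
  per table); other aggregations (mean, whole-matrix) are possible and
  would order methods the same way.
* **PCA summary** — top-2 principal axes of the z-scored features
  (correlation PCA; unscaled PCA would be dominated by volume-scale
  features), sign fixed so each component's largest-magnitude loading is
  positive.
* **BAcc / MCC** — balanced accuracy (mean of sensitivity and specificity)
  and the Matthews correlation coefficient, with the convention MCC = 0
  when any confusion-matrix marginal is zero.

## ML benchmark harness

Mirrors an external-validation workflow: harmonize the pooled cohort
(harmonization is unsupervised in the outcome), train on one batch, test on
the rest.  SMOTE (synthetic minority oversampling, k = 5 neighbours,
implemented in-package) balances classes on the training fold only; the
test fold is never resampled or seen during fitting.  Pipelines:

* **mr** — l1-penalized logistic regression with 10-fold cross-validated
  penalty over C in [1e-2, 1e1] (beyond that the selected set barely changes
  on near-separable oversampled folds but the solver cost explodes);
  features with nonzero coefficients are refit in an unpenalized logistic
  model (intercept-only fallback when nothing is selected).  The
  binary endpoint makes logistic regression the right "multivariate
  regression"; survival machinery is out of scope.
* **rf** — random forest with embedded selection: importances averaged over
  bootstrap refits, then stepwise forward selection over the ranking,
  stopping at the global minimum of out-of-bootstrap balanced error.
* **svm** — cost tuned first by cross-validation, features ranked by
  single-feature leave-one-out accuracy (linear kernel by default; on 1-D
  data the liblinear solver is used as an exact fast stand-in), then the
  same forward selection.

A strict `harmonize_train_only` mode fits the harmonization on training
rows only and re-applies the frozen model; it requires every batch to
appear in the training set, because the location-scale model cannot
extrapolate to unseen batches — which is also why applying a frozen model
to a single patient from a new center is out of scope.

## Synthetic cohorts

The generator implements the model above exactly, so the whole package is
testable with no patient data.  Feature baselines: means U(-5, 50), scales
U(0.5, 5), emulating heterogeneous physical units.  Batch effects are
injected in `sigma_g` units so effect sizes are comparable across features.
Two shift regimes are provided, because they exercise different aspects of
the method:

* **Heterogeneous** (scalar `gamma=s`: U(-s, s) per batch and feature, or a
  magnitude range with random signs): centers move in near-orthogonal
  directions of feature space — the regime for label discovery.  The
  across-feature effect distribution is kept continuous and bounded on
  purpose: distributions with sparse extreme order statistics (discrete
  levels, Normal tails) leave isolated features that the nonparametric EB
  integration drags toward their nearest neighbours, a genuine property of
  the method worth knowing about.
* **Homogeneous** (`shift_recovery_spec`: per-batch levels ±1.5 or ±2
  sigma with 0.15 sigma per-feature jitter; scale levels 0.8/1.0/1.25 with
  5% lognormal jitter): a center affects all features similarly — the
  regime the EB prior models, used for the elimination and recovery
  studies.  With fully heterogeneous shifts the prior is uninformative and
  no estimator can beat the raw batch mean (whose error at n = 50 already
  exceeds 0.1 sigma).

The binary outcome is logistic in the pre-batch-effect biology of a chosen
informative-feature subset, with the intercept solved numerically for the
target event rate, so outcome and batch are independent by construction
(`confounded_outcome` tilts per-batch rates to exercise the balance check).
Cohort presets mirror two study shapes: 3 batches of 119/50/28 samples with
173 features and a 34% event rate, and 2 batches of 60/38 with a 15% event
rate.  What the generator does *not* emulate: realistic marginal
distributions of texture features (heavy tails, skew), strong feature
correlation (only optional equicorrelation), missingness, or nonlinear
batch effects — passing tests show the machinery is correct under its own
model, not that real cohorts behave this ideally.

## Study sizes

The seeded studies use deliberately moderate sizes chosen to estimate each
quantity well: 3 seeds x 173 features for elimination, 20 seeds x (3 x 50
samples, 100 features, B = 100) for recovery, 20 seeds for label discovery,
10 seeds x (197 samples, 30 features, B = 40) for the ML benchmark with a
lean forest/bootstrap configuration (60 trees, 5 importance refits, 4
validation bootstraps, ranking prefix ≤ 5).  Library defaults are larger
(B = 1000, 500 trees, 100 importance refits).

## Known limitations

* No transform for samples from batches unseen at fit time.
* Grand-mode output is not exactly idempotent (see above).
* The nonparametric prior can visibly over-shrink isolated extreme batch
  effects (single features whose effect is far from all others').
* Aggregate COV is scale-sensitive: features with near-zero mean dominate;
  zero-mean features are excluded.
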