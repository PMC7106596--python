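# Methods

## Model

`qsprblend` fits a two-level *blending* ensemble to a descriptor table
(n samples × p numeric molecular descriptors, one continuous or binary
target). Blending is a simplified stacked generalization: instead of
out-of-fold predictions, the level-1 combiner is trained directly on the
level-0 models' predictions, which is simpler and carries less bookkeeping
at the cost of a potential information leak (see *Blend modes* below).

**Level-0 pool.** Four decision-tree ensembles spanning the two classic
strategies: bagging with full trees (random forest), bagging with
randomized cut-points (extremely randomized trees), adaptive boosting
(AdaBoost) and gradient boosting (GBM). They are consumed from
scikit-learn; the package owns the contract around them (validation,
deterministic seeding, name-aligned prediction, importance extraction),
not the tree algorithms themselves. At least two models are required; the
canonical pool is these four.

**Level-1 combiners and weights.** For n level-0 models with importance
vectors FIᵢ, the blend's interpretability rests on a weight vector w on
the probability simplex and the aggregate FI_blend = Σ wᵢ FIᵢ:

- *uniform*: no meta-learning. Regression averages predictions;
  classification takes a majority vote of hard labels. wᵢ = 1/n exactly.
- *linear*: multiple linear regression (regression) or logistic regression
  (classification) on the level-0 prediction matrix.
  wᵢ = |coefᵢ| / Σⱼ|coefⱼ|, intercept excluded. Absolute values are used
  because reported blend weights are nonnegative percentages while raw
  coefficients may be signed; the mapping from signed coefficients to
  published weights is not otherwise pinned down.
- *any*: a deliberately small gradient-boosting model
  (10 estimators; max_depth 8 and learning rate 0.1 for regression,
  max_depth 4 for classification — capacities suited to a 4-column input).
  wᵢ is its impurity importance over the n inputs, already a simplex.

For classification, the linear and any combiners receive level-0
*positive-class probabilities*, not hard labels: graded inputs are what a
logistic or GBM combiner needs. The uniform vote uses hard labels; an even
vote (possible with n = 4) resolves positive when the mean positive-class
probability is ≥ 0.5, then favours the positive class — votes are rarely
tied and no convention for them is established, so determinism was the
deciding criterion.

**Blend modes.** `holdout` (default, fraction 0.2): level-0 models are fit
on 80 % of the training data, the level-1 combiner on their predictions for
the held-out 20 % (class-stratified for classification), and the level-0
models are then refit on all training data. `insample` feeds training-set
predictions straight into the combiner — the flow that produces
near-perfect training fits, retained because it is the simplest description
of blending and useful for algebraic tests (e.g. in-sample OLS blending is
guaranteed not to lose to any single level-0 model on the training set).
Which mode a published table used is generally unknowable; neither mode
claims to replicate specific published train/test numbers. Holdout
fractions are limited to (0, 0.5] — a combiner trained on more data than
the base models see is not a blend.

**Degenerate fits.** If the level-1 fit is degenerate (constant
predictions on a non-constant target, all-zero coefficients, or a
single-class level-1 training window), the blend warns and falls back to
the uniform rule entirely — weights *and* prediction — rather than keeping
a useless combiner in the loop.

## Feature importance

Importance is mean decrease in impurity as exposed by the backing learner,
clipped at zero and renormalized to sum to 1 (renormalization is applied
only when drift exceeds 1e-9; the weighted sum is already normalized in
exact arithmetic). An all-zero vector (possible for a trivial ensemble)
falls back to uniform. Permutation importance and per-sample attributions
are out of scope.

Because impurity importances depend on the ensemble's random state, the
repetition protocol refits a model (or a whole blend) under a list of
seeds and averages the vectors elementwise; the default list is 0–9, i.e.
ten repetitions. Rankings sort descending by score with ties broken by
ascending feature name — published rankings never show ties, and
determinism is required for testing.

## Evaluation metrics

Regression: RMSE = sqrt(mean((y − ŷ)²)) in target units and
R² = 1 − SS_res/SS_tot. For a test set, SS_tot uses the *test-set* observed
mean (the dominant convention for predictive R²; the alternative —
training-set mean — is not offered).

Classification, from the confusion counts a (TP), b (FN), c (FP), d (TN):

    Acc = (a+d)/(a+b+c+d)      Pr = a/(a+c)       r = a/(a+b)
    F1  = 2a/(2a+b+c)          MCC = (ad−bc)/√((a+b)(a+c)(b+d)(c+d))

Zero-denominator conventions: MCC returns 0 with a warning (standard);
Pr/r/F1 are reported as undefined (None) and flagged. Percentages are
rounded half-up to one decimal for display; internal values keep full
precision. Printed result tables occasionally disagree with their own
confusion cells at the last decimal (run-averaging in the source tables);
this package always reports what the counts imply.

## Hyperparameter search

`tune_level0` draws candidates from a (config-overridable) grid —
n_estimators ∈ {50, 100, 200, 500}, max_depth ∈ {3, 5, 8, None},
learning rate ∈ {0.01, 0.05, 0.1, 0.2} for boosters — with a seeded
`ParameterSampler` and scores each by 5-fold CV (shuffled, seeded;
class-stratified folds for classification) using mean RMSE (regression,
minimized) or mean accuracy (classification, maximized). Ties keep the
earlier-sampled candidate, making selection fully deterministic given the
seed. `ParameterSampler` + `cross_val_score` is used instead of
`RandomizedSearchCV` precisely to make that tie-break explicit. Default
(untuned) hyperparameters are scikit-learn's; they are not claimed to match
any published tuned values, which were never printed in full.

## Splitting conventions

`split_train_test` puts floor(train_ratio · n) samples in train and the
remainder in test — 3786 samples at 3:1 give 2839/947. The default split
is plain random, not class-stratified: the published per-class partition
counts of the liquid-crystal study (2060/2780 train positives vs 779/1006)
are inconsistent with exact class stratification, so `by_class` exists but
is opt-in, as is `by_group` (e.g. per chromophore family). Strata with
fewer than 2 samples go to train with a warning. Categorical descriptors
(e.g. solvent species) are integer-encoded rather than one-hot so that
each chemical concept keeps a single importance score. Missing values are
rejected by default (curated descriptor tables are complete); `drop` is
available for user data and logs what it removed.

## Synthetic data

The generator emulates the *shape* of real descriptor tables — wide,
numeric, sparse signal — not their content. Features are independent
standard normal; the latent score is Σ βⱼxⱼ over `n_informative` planted
columns (default 5 of 100, β = 1) plus, by default, the product of the
first two planted features (an interaction term, because purely linear
targets understate the differences between tree ensembles), plus
N(0, noise_sd²) noise with noise_sd = 0.5 — moderate noise relative to the
unit effects. Default table size is 400 × 100, a typical
QSPR-study magnitude. Classification thresholds the noisy score at the
`positive_fraction` quantile (default 0.73, mirroring a realistic
liquid-crystal prevalence), so class counts are *exact* and
imbalance-sensitive tests are deterministic — unlike Bernoulli sampling.

What the generator does **not** emulate: descriptor correlation structure,
heavy-tailed or discrete descriptors (fragment counts), label noise, or
activity cliffs. A green feature-recovery test therefore establishes that
the importance-aggregation path works on separable signal, not that any
particular chemical dataset is interpretable.

## Numerical and testing choices

- All randomness flows from explicit integer seeds (numpy `default_rng`,
  scikit-learn `random_state`); seeds derived internally are reduced
  mod 2³¹−1.
- Simplex tolerances: importance and weight vectors must sum to 1 within
  1e-9; metric-oracle agreement is asserted to 1e-12.
- The seed-repetition average in the long-running feature-recovery check
  uses 3 seeds instead of the 10-seed default purely for runtime; the
  protocol is otherwise unchanged.
- CSV reads use pandas' round-trip float parser so write→read is exact.

## Known limitations

- Blending here is strictly two-level with a single combiner; full
  out-of-fold stacking and deeper stacks are out of scope.
- Only impurity importances are aggregated; they are known to favour
  high-cardinality/continuous features, and the blend inherits that bias.
- The linear-weight convention (absolute coefficients) makes w invariant
  to a sign-flipped combiner but discards the information that a level-0
  model entered negatively.
- Published real-data performance tables depend on commercial datasets and
  stochastic tuning and are not reproduced by this package's test suite;
  the optional integration script reports, never asserts.
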