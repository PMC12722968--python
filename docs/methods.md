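# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions in `pdpipe`, in the package's own words.

## Preprocessing (z-score normalization)

Column statistics use the **population** standard deviation
(divide by the number of present records, not n−1); the z-score has an
explicit two-branch definition so zero-variance features degrade to plain
centering instead of dividing by zero. The subsequent min-max step rescales
the z-scores of each feature to [0,1] using the observed z-score range; a
constant feature maps to 0 everywhere. The composition is invariant to
positive affine rescaling of any input feature (tested to 1e-10), which is
the property that makes the pipeline indifferent to the heterogeneous units
of dysphonia measures (Hz, dB, dimensionless ratios).

Record cleaning has three stages with recorded reasons per dropped row:

1. rows whose missing-cell fraction exceeds `max_missing_frac` (default
   0.2) are dropped (`drop_row` drops any row with a missing cell);
2. remaining gaps are imputed with the column mean over present records;
3. rows containing any |z| > `z_cutoff` (default 4) are dropped as
   carrying irrelevant values. Removing an outlier changes the column
   statistics, so this step recomputes and repeats until no row is
   flagged. The fixed-point definition is what makes cleaning exactly
   idempotent; the practical cost is that a borderline row can be removed
   in a later sweep once a grosser outlier no longer inflates the SD.

The cutoff 4 is a deliberately conservative default for data whose
"irrelevant values" are data-entry errors or failed feature extraction
rather than biological variation; it is configurable. When the pipeline
evaluates on held-out partitions, cleaning is applied per partition but the
z-score and min-max statistics are **fit on the training partition only**
and reused (held-out values are clipped to [0,1]); `fit_on: all` restores
collective normalization for comparison, at the price of information
leaking from test rows into the scaling.

## Feature weighting (class-separation statistic)

B_A is a Welch-type standardized class-mean difference: absolute mean gap
over the pooled standard error with **sample** (n−1) class variances —
hence the requirement of at least two rows per class. Guards: if both class
variances vanish, B_A is 0 when the means agree and the gap divided by
1e-12 when they differ (so a perfectly separating constant-within-class
feature dominates, as it should); if *no* feature separates the classes,
weights fall back to uniform 1/T_A with a warning rather than an error.
W_g is a simple sum-normalization, which makes it scale-free,
permutation-equivariant, and monotone in the mean separation. The error
rate entering F2 defaults to 0.05 and is explicit configuration — F2 is
reported alongside W_g but nothing downstream consumes it by default.

## Feature selection (information gain + logistic decision)

Discretization is equal-frequency with 10 bins by default, chosen because
dysphonia features are strongly skewed and quantile bins are invariant to
monotone transforms (up to ties). Features with at most `n_bins` distinct
values are binned by value instead: quantile edges on heavily tied data can
collapse informative levels into a single bin (a binary feature with a 2:1
imbalance has its median at the majority value), and distinct-value binning
keeps the perfect-predictor identity IG = H(Y) exact for any class balance.

The logistic decision standardizes the gains across features (population
SD; an all-equal gain vector maps every score to exactly 0.5, with a
1e-12-relative tolerance because floating-point SD of identical values is
not exactly zero) and applies a sigmoid. Under this reading the selection
threshold 0.85 means "gain about 1.73 SDs above the across-feature mean" —
a strict filter that, on a table where no feature stands out, would select
nothing; the top-k fallback (k_min = 4, matching the four canonical voice
markers PPE, spread1, D2, MDVP:RAP) guarantees the classifier always
receives input, and the fallback is recorded in the gain table.

Mutual information for the final ordering is computed from the joint
bin/label count table rather than by reusing the conditional-entropy code;
the two estimators are mathematically identical under the same binning, and
the equality is asserted in the tests (together with an external
cross-check against scikit-learn's `mutual_info_score`). DASR weights do
not gate selection by default — the two stages are chained narratively, not
algebraically; `combine: gain_times_weight` exposes the product variant.

## Classifier (fuzzy neural network)

The network is described in the Mamdani If-Then idiom but its printed rule
consequents are linear functions of the inputs, i.e. Takagi–Sugeno form; we
implement the equations (linear consequents, normalized weighted-average
aggregation) and keep the conventional name only in prose. Architecture
per forward pass, for d selected features and R rules:

* memberships mu_{r,j} = exp(−(x_j − c_{r,j})² / 2 z_{r,j}²), computed in
  log-space for the product t-norm so 22-feature antecedents cannot
  underflow individually;
* firing strengths w_r (product t-norm by default; min available by
  config but not differentiable, so gradient training requires product);
* rule outputs R_r = p_r·x + q_r; normalized weighting g_r = w_r/Σw with a
  uniform-firing guard when Σw < 1e-300;
* class head: logits = V (g ∘ R) + b, softmax over 2 classes.

The membership-width symbol is distinct from the consequent bias even
though conventional notation overloads them. Initialization is data-driven
and deterministic given the data: rules alternate classes; a rule's centers
are per-class per-feature quantiles at (k+½)/K (class medians when K=1);
widths are half the inter-center spread per feature, floored at 0.05 on the
[0,1] scale so no membership collapses to a delta; consequents start at
zero; the class head is small seeded Gaussian noise — the only stochastic
element, needed because a zero head would block gradient flow into the
consequents.

Training is full-batch gradient descent on the mean softmax cross-entropy
over all six parameter groups, with the momentum update
Δ_new = −τ·grad + α·Δ_prev, θ += Δ_new (an alternative literal reading in
which the second term shrinks the weight itself, θ_new = −τ·grad + α·θ, is
available as `update_rule: literal` for comparison). Defaults: τ = 0.6
(midpoint of the 0.4–0.8 range the update rule is specified for; values
outside warn), α = 0.9, 300 epochs, early stop after 30 stagnant validation
epochs with best-validation weights restored, width floor re-applied after
every step. Analytic gradients are verified against central finite
differences (relative error < 1e-4) in the test suite. Full-batch updates
make training exactly invariant to row order under a fixed seed.

Risk stratification maps the PD probability through two thresholds
(defaults 0.33 / 0.66) into low / medium / high classes; the hard label cut
stays at 0.5 regardless of the risk bands.

## Evaluation

All metrics are on the percentage scale (precision, recall, accuracy,
false rate = (FP+FN)/n·100; F1 is the harmonic mean of percentage P and R,
identical to fraction-scale F1×100). Zero-denominator metrics are reported
as explicit `undefined` markers, never as silent zeros, because imputed
zeros corrupt cross-model comparisons. The comparison harness shares
identical splits across models, records failed fits without aborting, and
offers an exact binomial test on the discordant correct/incorrect pairs of
two models (a McNemar-style exact test) — a documented procedure of this
package, not a reproduction of any published significance analysis.

## Synthetic data

The generator emulates the *statistical* structure the pipeline assumes,
not acoustics: informative features are class-conditional Gaussians whose
means differ by `effect_size` pooled SDs; noise features are equicorrelated
Gaussians (pairwise correlation 0.2 by default — weak cross-measure
correlation of the kind repeated perturbation measures show) with no class
signal; each column then receives a random location/scale (U(−5,5),
U(0.5,3)) standing in for heterogeneous units; missingness is injected
completely at random, never touching labels. Defaults (400 rows, 4
informative of 22 features, effect size 2.0, balanced classes) mirror the
regime the experiments use. What passing tests on this substrate shows:
the stages recover planted separation/information structure and the
classifier learns separable classes. What it does not show: robustness to
real dysphonia data's heavy tails, label noise, batch effects, or
informative missingness — none of which the generator emulates.

The 12-row worked toy (two informative, two noise features, six rows per
class, hard-coded values) is the cross-module fixture on which all exact
oracle equalities (1e-12) are asserted.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` use n = 200–1,000 rows,
10–50 seeds per Monte-Carlo claim, and 22 features — sizes at which every
stage's statistical claims (feature recovery in ≥ 90% of seeds, held-out
accuracy ≥ 95% on separable data, chance-level accuracy after label
shuffling) are sharply testable while the full suite runs in seconds.

## Known limitations

* Two-class only; no multiclass head, no per-class normalization.
* The min t-norm is inference-only (not differentiable).
* Equal-frequency binning with 10 bins is a fixed estimator; no bias
  correction is applied to the information-gain estimates (the independent-
  feature bias at n = 2,000 is bounded in the tests at < 0.02 bits).
* Cleaning's outlier rule is univariate; multivariate outliers pass.
* With heavily imbalanced classes the stratified split requires at least
  one row of each class in every partition and errors otherwise.
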