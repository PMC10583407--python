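# Methods

## Model

The classifier is a two-part network. An elementwise gating layer
`y_i = w_i x_i` (one weight per input index, initialized at 1) feeds a
log-linearized Gaussian mixture network (LLGMN). The LLGMN expands its input
to `X = (1, y, {y_i y_j}_{i<=j})` — dimension `H = 1 + P + P(P+1)/2` — and
applies a single linear layer with one column per (class, component) unit,
followed by a softmax over all `C·M` units; class posteriors are sums of unit
outputs within a class. The last unit's weight column is pinned to zero
(identifiability anchor; the softmax is shift-invariant, so this loses no
expressiveness). Since `log [pi N(x; mu, Sigma)]` is a quadratic form in `x`,
the family contains every Gaussian-mixture Bayes classifier exactly;
`log_linearize_gmm` performs that construction and is the oracle used to test
the forward pass.

Training minimizes the energy `E = summed cross-entropy + lambda * ||w||_1`
end to end. The L1 term is handled proximally: after each mini-batch SGD step
the gates receive soft-thresholding with threshold `learning_rate * lambda`.
This is what makes gates *exactly* zero (a subgradient method would only make
them small). A zero gate multiplies its column away: model output is exactly
invariant to that index, which the permutation-importance code exploits
(PI of a zeroed index is identically 0 without computing any shuffle).

Because every expanded entry is a monomial, `expand(w*x) = expand(x) *
expand_pattern(w)` elementwise; training therefore expands the data once and
folds the gates in per step, which dominates the speedup over a naive
implementation.

## Training protocol and defaults

- SGD, learning rate 0.01, batch size 50, up to 10,000 epochs; early stopping
  when the full-data energy fails to improve by more than 1e-4 for more than
  5 consecutive epochs; best-energy parameters are returned. The monitored
  loss is the full-data energy recomputed after each epoch (the protocol's
  granularity is otherwise ambiguous; epoch-level is the stable choice).
- Cross-entropy is a **sum** over samples, not a mean, so lambda scales with
  N. Posteriors are clipped at 1e-12 before logs; softmax uses
  max-subtraction.
- LLGMN weights start at zero (uniform initial posteriors, reproducible);
  gates start at 1 (identity layer). No positivity constraint on gates.
- Number of mixture components M defaults to 1 (C = 2 classes throughout).
  With M = 1 the LLGMN is a convex logistic model on the expanded features,
  which is also why the lambda = 0 / unit-gate configuration reproduces plain
  LLGMN training at convergence (the gating layer is absorbable by
  rescaling).
- lambda is tuned by a tree-structured Parzen estimator over log-uniform
  [1e-5, 10] (100 trials by default, fewer in the packaged studies), with a
  stratified inner-CV mean out-of-fold cross-entropy objective. The TPE is a
  compact in-package implementation: good/bad split at the 25% quantile,
  Gaussian-kernel Parzen densities in log-lambda, candidates drawn from the
  good density and scored by the density ratio; 10 random startup trials; one
  seeded RNG end to end.

## Cross-validation, selection, importance

Folds are stratified with per-class counts differing by at most one per fold
and remainders dealt to the smallest folds, so 55 samples over 11 folds gives
eleven folds of exactly five. Standardization (sample SD, n-1) is computed on
each fold's training rows and applied to its validation rows; a column that
realizes constant within a training fold is centered and left at zero
variance rather than raising (binary indices with extreme proportions make
this reachable at cohort scale). The public `standardize` keeps the hard
error by default.

Selection follows the non-zero-at-least-once rule: the union of exact-support
across folds. Ranking uses the fold-mean of |w_i| (signs can disagree across
folds; signed means are reported alongside). Permutation importance shuffles
one validation column at a time (one seeded shuffle per index per fold by
default, a `repeats` knob averages several) and reports the fold-mean of
`e_i - e` with the same clipped-log summed cross-entropy as training.

## Baselines

- **Stepwise partial-KLI elimination.** Partial KL information is
  operationalized as the increase in validation cross-entropy when one input
  column is replaced by its training-fold mean (zero after standardization);
  the published formulation of the original stepwise criterion is not
  reproducible from available sources, so this mean-substitution variant is
  isolated behind one function and recorded in run metadata. Each round
  cross-validates a plain LLGMN on the remaining indices, pools out-of-fold
  posteriors into an AUC, removes the index with the smallest fold-mean
  delta, and stops at one index; the retained set maximizes AUC along the
  trace (ties resolve toward the smaller set). The trace's importance ranking
  is reverse removal order. A Table-6-style leave-one-index-out AUC-reduction
  table (`auc_drop_importance`) is available separately; reductions may be
  negative.
- **Lasso.** Penalized *linear* regression of the 0/1 label on standardized
  predictors (deliberately not logistic), solved by cyclic coordinate descent
  to 1e-8; coefficients on standardized predictors are the standardized
  partial regression coefficients used for ranking. lambda comes from a
  5-fold inner CV minimizing squared error over a 30-point geometric grid
  from lambda_max down three decades (plain minimum, no one-SE rule).

All methods in a pipeline run share one fold assignment, so out-of-fold
scores are paired and the DeLong comparisons are valid paired tests.

## Evaluation statistics

AUC is the tie-aware pairwise concordance (equals the trapezoidal area);
thresholds are midpoints between consecutive distinct scores with +-infinity
sentinels; the operating point maximizes sensitivity + specificity with ties
broken by higher sensitivity then lower threshold. ROC curves are built from
pooled out-of-fold scores (one curve per method, matching one reported AUC),
not averaged per fold. DeLong variance/covariance uses placement values; a
zero-variance difference returns p = 1 with a warning. Fisher's exact test
and the Brunner-Munzel statistic delegate to scipy (the relative effect
P(A<B) + 0.5 P(A=B) is computed locally via midranks); Holm adjustment
delegates to statsmodels. Yule's Q = (ad-bc)/(ad+bc) is NaN-with-warning when
ad+bc = 0.

## Synthetic data

- **Cohort mode** draws independent per-index values: continuous indices
  Normal(group mean, group SD), binary indices Bernoulli(group proportion),
  with group sizes (41, 14) and 65 indices in the bundled specification of
  published per-group summary statistics. The three per-limb motor-recovery
  (BRS) entries are synthetic stand-ins derived from the published discharge
  total (mean total/3, SD total/sqrt(3)); they are marked as such in the spec
  file. Optional equicorrelation blocks (shared standard-normal factor) let
  tests probe correlated predictors; no truncation to clinical ranges by
  default (standardization makes ranges immaterial), a clip option exists.
  What this mode does **not** emulate: the real joint correlation structure
  among indices (unknown), non-normal marginals, and any structural link
  between indices and outcome beyond the group-wise shifts. A pipeline that
  scores well here demonstrates workflow correctness, not clinical accuracy;
  published AUC/selection results are not recoverable from summary
  statistics and are not targeted.
- **Sparse-signal mode** is the ground-truth harness: N=200 samples, P=30
  columns, k=5 informative with the lead index at the full standardized mean
  difference d=1.5 and the others at 0.6·d = 0.9, remaining columns pure
  noise (optionally equicorrelated). The 0.6 fraction is a deliberate design
  point: pilot runs with strongly decaying effects showed that out-of-fold
  cross-entropy is genuinely minimized by pruning sub-0.7-SD gates — correct
  regularization behavior that would make "recover the planted support" an
  ill-posed benchmark — while a single shared effect leaves "the strongest
  planted index" undefined for rank-based checks. Labels depend only on the
  class split, never on realized noise.

## Problem sizes used in the packaged studies

The recovery study runs 10 generator seeds with TPE at 15 trials over a
3-fold inner objective, 5 outer folds, and 500-epoch training; the
cohort pipeline uses 11 folds, 20 TPE trials and 200-epoch training; the
stepwise baseline uses 3 folds and 100-epoch training on the fixture. These
sizes keep a full run in minutes on one CPU while leaving every qualitative
conclusion unchanged at larger budgets.

## Known limitations

- Multi-class (C > 2) is untested beyond what the generic formulas provide.
- The stepwise baseline's mean-substitution criterion is one defensible
  operationalization of partial KLI, not the only one.
- TPE in the pipeline defaults to one global tuning pass on the full table
  (recorded in the report); per-fold tuning is available but multiplies cost
  by K x trials.
- Selection reuses the same folds that produce the reported AUC; as in the
  motivating study design, this is not an unbiased estimate on unseen data.
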