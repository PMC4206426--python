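# Methods

## Problem and model

The task is binary classification of candidate A-to-I RNA-editing sites
from a fixed table of real-valued per-site alignment features (the
editing/positive class versus non-editing/negative).  The pipeline is a
filter-style feature-selection protocol wrapped around a random forest:

1. discretize features, rank all N of them by the greedy
   maximum-relevance / minimum-redundancy (mRMR) criterion;
2. trace an incremental-feature-selection (IFS) curve: for every
   k = 1..N, cross-validate a forest on the top-k features;
3. pick the optimal k by the Matthews correlation coefficient (MCC) and
   train the final forest on the full training set restricted to those
   features.

MCC is the primary evaluator because the natural test populations are
heavily imbalanced (e.g. 533 positives vs 90 negatives), where accuracy
alone is uninformative.

## Discretization and information estimates

mRMR needs discrete variables.  Each continuous column is mapped to
three states at mean ± t·sd: +1 above, −1 below, 0 between, with
population (1/n) standard deviation and t = 1 by default
(`threshold_multiplier`).  This is the convention of the classic mRMR
implementation; the protocol itself does not prescribe a discretization,
so it is a documented package choice.  Consequences:

* a constant column (sd = 0) maps to all zeros and has zero relevance;
* columns that are already discrete — at most `passthrough_levels` = 3
  distinct values, e.g. a 0/1 repeat-region flag — bypass thresholding
  and keep their own alphabet (mutual information is invariant to state
  relabeling, so the re-encoding to consecutive integers is harmless).

Entropy and mutual information (MI) are plug-in estimates in bits
(log base 2); MI is computed as H(x) + H(y) − H(x, y) and clamped at 0
against roundoff.  Rankings under MID are invariant to the log base
(uniform rescaling of all scores); MIQ is exactly invariant.  No
continuous (k-NN/kernel) MI estimators and no adaptive binning: with
n ≈ 250 samples and 3-state variables the plug-in estimator is the
transparent, reproducible choice.

## mRMR ranking

Greedy forward scan over all N features.  Step 1 picks
argmax I(f; y).  Step k > 1 picks, among unselected f,

* MID (default): I(f; y) − mean over selected s of I(f; s)
* MIQ: I(f; y) / max(mean redundancy, ε), ε = 1e−12

Ties break to the lowest original column index (deterministic).  The
first pick is scheme-invariant.  MID is the default because it is the
baseline "difference" form of the criterion; which form the original
protocol used is unstated, so reports always echo the scheme.
Redundancy bookkeeping is incremental (selecting s adds I(f, s) to each
remaining candidate's running sum); tests verify it against a
from-scratch exhaustive step scan.

## Random forest

Defaults mirror Weka 3.6.4's RandomForest, the learner the protocol was
designed around: 10 trees, unlimited depth, bootstrap row sampling, and
⌊log₂ M⌋ + 1 candidate features per split where M is the active feature
count.  The ensemble is scikit-learn's `RandomForestClassifier`
(Gini impurity; Weka splits on information gain — tree-level agreement
across ecosystems is not attainable, metric-level agreement is the
fidelity target).  Prediction is a hard majority vote over trees,
implemented on top of the fitted ensemble because scikit-learn's own
`predict` soft-votes averaged probabilities; an exact vote tie (possible
with an even tree count) resolves to the negative class so predictions
are deterministic.  Ten trees keep the historical behavior but make
cross-validation estimates noisy; `n_trees=100` is recommended when
fidelity to the original protocol is not required.

## Cross-validation and metrics

Stratified 10-fold CV by default, folds drawn by seeded shuffling
within each class (scikit-learn `StratifiedKFold`); stratification is
the package's choice — the protocol says only "randomly split", but the
training set is exactly balanced and Weka's CV stratifies.  "Iterated
10 times" is read as the 10 fold-rotations of a single 10-fold CV;
`repeated_cross_validate` provides independent repeats for variance
estimation.

Fold predictions are pooled into one confusion matrix over all samples
and the metrics computed once (micro-averaging).  With ~25-sample folds
the per-fold MCC is unstable and its mean is biased toward 0; pooling
matches reporting a single Sn/Sp/Acc/MCC row per k.  Mean-of-folds is
available (`pooled=False`).  Conventions for degenerate counts: MCC = 0
when any denominator factor is zero; Sn (Sp) is NaN when no positives
(negatives) were evaluated, and NaNs are excluded from fold averaging.
The MCC numerator and denominator product are computed in exact integer
arithmetic before one square root, so large counts cannot overflow.

## IFS

The same fold assignment is reused for every k (paired comparison —
curve differences between adjacent k reflect the added feature, not
fold noise); per-k independent folds are available.  The optimal k is
the smallest k attaining the maximum MCC (parsimony tie-break).  The
curve's k = N point equals a direct CV call on all features with the
same seed, a consistency invariant under test.  The full N-point curve
is always computed (N = 77 costs ~10 s single-core).

A caveat established during validation: when the informative signal is
strong, the MCC curve is a flat plateau beyond k = (number of
informative features), and the plain argmax can land anywhere on the
plateau under CV noise.  The selected k is therefore best read as "at
most this many features are needed", not a sharp estimate of the number
of informative features; a one-standard-error rule would sharpen it but
is deliberately not applied, to keep the selection rule the protocol's
own.

## Synthetic data

`SyntheticSpec`/`generate` plant a known structure: informative
features are Normal(0, 1) in the negative class and Normal(δ, 1) in the
positive class; redundant features are copies of informative ones plus
Normal(0, `redundant_noise_sd`) jitter; noise features are Normal(0, 1)
in both classes.  Defaults reproduce the study's dimensions — 127
samples per class, 77 features (3 informative + 2 redundant + 72
noise), δ = 2, jitter sd 0.1 — so the pipeline is exercised end-to-end
at realistic scale with no external data.  δ = 2 makes single features
individually informative after 3-state discretization (comparable to
the strongest real alignment features); δ = 0 gives an exact null for
calibration.

What the generator does **not** emulate: the heavy-tailed,
zero-inflated distributions of real count-ratio features, correlations
among noise features, label noise, and test-set class imbalance.
Passing tests on synthetic data therefore demonstrate that the
machinery (ranking, redundancy penalization, curve tracing, selection,
evaluation) behaves correctly, not that any particular accuracy will be
achieved on real editing data.

## Numerical and I/O choices

* Delimiter sniffing (`,`, tab, `;`) on the header row, overridable.
* Label mapping: values are normalized (so `1`, `1.0`, `" 1"` agree)
  and compared to `positive_label` (default "1"); remaining values must
  agree on one negative code unless `negative_label` is given.
* Missing feature values are a hard error; median imputation is opt-in.
* Table round trips are lossless: floats are written at shortest
  round-trip precision and parsed with pandas' `round_trip` parser.
* IFS curves serialize metrics at 6 decimals (4 are needed to recover
  curve maxima exactly); reports print 3 decimals but store full
  precision.
* All randomness (fold shuffles, tree seeds, generator draws) flows
  from explicit integer seeds; identical configuration + seed gives
  byte-identical ranking and curve files.

## Problem sizes used in the test suite and acceptance script

Unit and property tests run on 12–60-sample hand-built or synthetic
tables; end-to-end checks use the full 254 × 77 study dimensions (one
IFS sweep ≈ 10–15 s); recovery and null-calibration studies use 20
seeds each at n = 200–254.  These sizes were chosen so the whole suite
completes in a few minutes single-core while every claim is still
exercised at the scale it is made about.

## Known limitations

* The published feature ordering (ranks 1–18 of the original table)
  is not guaranteed to be reproduced exactly: the original mRMR
  discretization and scheme are unstated, and the ranking is sensitive
  to both.  Metric-level agreement windows are the stated target.
* Ten-tree forests make individual CV points noisy; the IFS argmax
  inherits that noise (see the plateau caveat above).
* No probability calibration, no AUROC/PR reporting, no nested CV for
  selection-bias correction: the IFS training-CV optimum is an
  optimistically biased estimate by construction, which is why an
  independent test table is part of the workflow.
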