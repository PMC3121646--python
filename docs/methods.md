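# Methods

## The precision-index model

Let a classifier emit posterior class-membership probabilities p(c|x) for
C classes and define MaxP(x) = max_c p(c|x).  For a set of scored
predictions with known truth, the tail precision at threshold a is

    Pindex(a) = #correct in {x : MaxP(x) ≥ a} / #{x : MaxP(x) ≥ a}.

The working assumption is that confidence orders precision: Pindex should
be non-decreasing in a.  Observed tail precisions are noisy and can be
locally non-monotone; the Precision Index PIN is the weighted isotonic
(non-decreasing least-squares) regression of the observed per-record tail
precisions Pindex(MaxP(x_i)) on MaxP(x_i).  Records tied in MaxP share the
same tail precision by construction, so they are pooled to one knot with
weight equal to the multiplicity; this reproduces the record-level fit
exactly and makes the fit a function of the threshold.  Between knots PIN
is evaluated by linear interpolation; outside the observed range it clamps
to the endpoint values, which preserves monotonicity and the [0, 1] range.
Where the data contradict monotonicity the fit is constant over the pooled
region — there MaxP carries no ranking information and the constant is the
pooled precision.

Two properties of the isotonic fit are load-bearing and tested: it equals
the exhaustive-search minimizer of weighted squared error over all
monotone fits, and it conserves the weighted mean of its targets.

The isotonic target is the observed tail precision, not the 0/1
correctness indicator.  The two differ in weighting (tail precisions are
cumulative averages); this package implements the tail-precision
formulation throughout.

PIN is an estimated precision, hence comparable across arbitrary models.
The combined classifier (PINCom) classifies each instance into the
predicted class of the model with the highest PIN; ties are broken
uniformly at random from a dedicated seeded stream, so the combined
classifier is reproducible independently of learner seeds.  Its
confidence score MaxPIN = max_m PIN_m(x) plays the role of MaxP.

The class-specific precision index PIC repeats the tail-precision
construction inside one predicted class, as a function of PIN: for class
k, P_k(a) is the precision of {x : predicted(x) = k, PIN(x) ≥ a}, fitted
isotonically over the PIN knots, and PIC(x) = P_k(PIN(x)).  Classes with
fewer than 3 predictions get a constant curve equal to their class
precision (an isotonic fit on 1–2 points is vacuous); a class never seen
among the calibration predictions falls back to returning PIN unchanged,
with a warning — conservative, since PIC exists to *sharpen* PIN.

## Recall–precision curves and inversion

For any of the scores (MaxP, PIN, MaxPIN, PIC), the raw curves
P(a) = precision and R(a) = recall of {score ≥ a} are step functions on
the distinct observed score values.  At the lowest threshold both equal
the overall precision of the full set — this identity is exact on the raw
curves and is asserted as such.  The smoothed curves are the isotonic (P)
and antitonic (R) weighted fits with linear interpolation; because pooling
averages neighbouring knots, the smoothed value at the lowest knot may
differ slightly from the raw full-set precision.  Threshold inversion
operates on the smoothed curves: for a target precision it returns the
*smallest* qualifying threshold (the largest subset at that precision),
for a target recall the *largest* threshold retaining it; unreachable
targets raise errors that report the achievable maximum.

Class-specific curves use a different recall denominator — all instances
whose true class is k — so the full-set identity applies only to overall
curves.

A score that is independent of correctness should produce a flat curve.
This is a property of scores with genuinely supported thresholds: with a
continuous score the top knot is a single Bernoulli record and the
isotonic fit follows it to 0 or 1 with probability 1/2 at any sample
size.  The flatness test therefore uses a discrete noise score (19
levels, n = 2000), matching the finite resolution of real classifier
outputs.

## Resampling protocols

PIN fitted on in-sample predictions is optimistic, so fitting uses
out-of-fold predictions: K repeats of (stratified) 10-fold
cross-validation produce K × n records per model, all models sharing the
identical partitions (paired design).  Models are then refit on the full
training data, test MaxP values are mapped through the fitted PIN
functions, and PINCom is formed on the test predictions.

Evaluation uses double cross-validation: an outer 10-fold loop holds out
10% while the entire PIN-estimation stage (inner K-repeat CV, PIN and PIC
fits, combination rule) runs on the remaining 90%; the outer-fold models
score the held-out 10% through the inner calibrations.  The full pass
repeats KK times, yielding KK × n predictions per model and for PINCom in
which no instance ever influenced its own calibration; an audit trail of
calibration/holdout instance sets per fold is retained and checked.
Inner PIN functions are refitted in every KK repeat.

Defaults follow the study design this package emulates: 10 folds, K = 20
(20–50 acceptable), KK = 10.  Folds are stratified by class by default —
with classes as small as 8 instances, unstratified 10-fold splits can
strand a class entirely outside a training fold; `stratified=False`
restores literal random partitioning.  The stratified partitioner deals
each class's shuffled indices round-robin into folds from a random
offset, so every fold complement retains all classes of size ≥ 2.

When test truth is unknown, the double-cross-validated smoothed precision
P_xv(a) estimates the correct count in a test subset {PIN ≥ a} as
size × P_xv(a); thresholding on PIC uses the class-specific curves,
|{PIC ≥ a, predicted = k}| × P_k(a) summed over classes.  Estimated
precision and recall follow by dividing by subset size and test size.

## Base learners and oversampling

Any estimator with a fit/predict-probability contract can register in the
learner registry.  Shipped defaults: random forest, radial-kernel SVM,
multilayer perceptron (averaged over repeated runs with distinct seeds —
the classical stabilisation for neural networks), k-nearest-neighbour
with neighbour vote fractions as probabilities, multi-response linear
regression (per-class 0/1 indicators regressed by least squares; fitted
responses clipped to [0, 1] and renormalised), Gaussian naive Bayes and
linear discriminant analysis.  The last two are cheap, well-calibrated
learners well suited to protocol-scale runs.  Probabilities are floored
at 1e-12 and renormalised before MaxP extraction, guarding learners that
emit exact zeros.

Oversampling duplicates each smaller class up to the largest class size:
whole copies followed by the first (max mod size) instances in original
order.  Duplicates are exact copies; the operation is idempotent.

## Combiner baselines

Vote takes the plurality class, ties broken by a seeded uniform draw.
Stack 1 regresses each class's 0/1 indicator on the concatenated level-0
cross-validated probability blocks by plain least squares (minimal-norm
solution with a warning when the design is rank-deficient — note the
intercept is always collinear with row-stochastic blocks) and predicts by
argmax of fitted responses.  Stack 2 trains a random forest on the
probability blocks plus one-hot encodings of the level-0 predicted
classes.  The contribution analysis rebuilds PINCom with each model
withheld and reports the recall difference at fixed precision levels;
negative entries mean the combination does better without that model.

## Synthetic data

The generator draws classes from spherical Gaussians N(mean_k, σ²I) with
exact per-class counts (no multinomial jitter, so bookkeeping invariants
are exact).  The default design emulates the motivating study: 21 classes
with sizes 8–50 summing to 367 instances, 60 features.  Class means sit
on random directions at distance `base_separation` × per-class
separability multipliers (default linspace 0.5–2.0), giving heterogeneous
class difficulty.  The shared spherical covariance keeps the Bayes
posterior closed-form — p(k|x) ∝ size_k · N(x; mean_k, σ²I) — providing
an exactly calibrated reference classifier for calibration tests.

Expert pseudo-models engineer complementarity: given a partition of the
classes, model m outputs the exact Bayes posterior wherever the Bayes
argmax falls in its specialty and otherwise blends the posterior with a
flat-Dirichlet random row (blend weight = noise level, 0 recovers the
oracle exactly).  Off-specialty predictions drift to chance with shrunken
confidence while specialty predictions stay perfectly calibrated, which
is the regime in which the combined classifier must strictly beat every
individual model.

What the generator does *not* emulate: correlated features, heavy tails,
label noise, or multi-label structure of real expression data.  Passing
tests demonstrate the method's internal correctness and its behaviour
under its own assumptions, not performance on any real dataset.

## Problem sizes and numerical choices

Protocol-scale tests and the acceptance script run the default 367 × 60
design with fast learners and reduced repeat counts (K = 1–10, KK = 2) —
sizes chosen so the whole suite completes in well under a minute while
still exercising every code path at the study's dimensions; the
paper-scale defaults (K = 20, KK = 10) remain the configuration defaults.
Isotonic fits use squared-error loss.  Argmax ties in posteriors break
toward the lowest class-vocabulary index; random tie-breaks in combiners
use dedicated seeded streams.  A master seed derives independent streams
for partitioning, learner fits and tie-breaks, so every pipeline stage is
reproducible in isolation.

## Known limitations

- PIN calibration quality degrades where MaxP has little support (very
  high thresholds); clamped extrapolation is conservative but flat.
- PIC for rare classes rests on few predictions; the constant fallback
  below 3 predictions trades resolution for stability.
- Stack 1 is deliberately unregularised; with many classes and few
  instances it overfits (that behaviour is part of what the baselines are
  meant to show).
- Multi-label classification is out of scope; each instance carries one
  class.
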