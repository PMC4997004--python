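# Methods

This note documents the models, conventions and design choices behind
`phonemood`, in the order data flows through the pipeline.

## Raw streams and event inference

Two channels are sampled: the telephony call state every `sample_period`
seconds (default 3 s) and the foreground app package name.  Samples are
left endpoints of `sample_period`-second occupancy intervals, so a run of
samples ends at its last sample plus one period — a single-sample event
has duration 3 s rather than zero.  A gap longer than `2 × sample_period`
(one dropped poll) closes any open run; real collectors drop samples, and
tolerating exactly one missed poll is the smallest forgiving rule.  All
intervals are half-open `[start, end)`.

Call events follow the telephony state graph.  A `ringing` run answered
by `offhook` becomes a call-in whose duration covers only the off-hook
span (ringing time is not talk time and is not emitted separately); a
`ringing` run returning to `idle` is a missed call over the ring span;
`offhook` entered from `idle` is a call-out.  App sessions are maximal
runs of one package; their union, merged across gaps of at most
`2 × sample_period`, is the screen session.  The streaming inference is
cross-checked in the tests against an independent per-second
reconstruction oracle.

## Emotion categories

VAS values live on the integer range 0–100.  Categories are fixed equal
thirds — low `[0, 100/3)`, medium `[100/3, 200/3)`, high `[200/3, 100]` —
with the upper category winning at a cut point.  Per-user empirical
tertiles were rejected: the evaluation phase must categorize predictions
before any evaluation-phase data exists, so the cut points cannot depend
on incoming data.  Users need at least 40 training tags to be admitted.

## Windowed features

For each tag and timeslot width w ∈ {0.5, 1, 1.5, 2} h, each usage type
contributes four statistics over `[t − w, t)`.  Events straddling the
window boundary are clipped rather than excluded, so duration statistics
reflect exactly the in-window usage; the inter-event interval uses the
events' own endpoints (which, for contributing pairs, lie inside the
window) and is 0 when fewer than two events contribute.  Empty-window
statistics default to 0 — this keeps the design matrix dense and every
classifier defined; zero-variance columns are retained but flagged, and
their handling is left to feature selection (a constant column can never
have a defined t statistic and is never auto-selected).

## Feature selection

The three categories are reduced to two binary contrasts ("levels"):
{low} vs {medium, high} and {low, medium} vs {high} — one cut below and
one above the middle category.  The first filter is a Welch
(unequal-variance) t test per feature per level, keeping features with
P < .05 at either level and filling to at least five features by smallest
min-over-levels P.  The second uses the pooled-variance t statistic with
deletion semantics: start from all features and delete those with
P < .05 at either level (a small P marks a feature whose groups differ);
if deletion empties the set the five largest-P features are retained so a
classifier can still be fitted.  No multiple-testing correction is
applied in either filter.

The wrapper searches score a feature subset by 5-fold stratified
cross-validated accuracy of the same classifier family being evaluated,
with folds fixed by a seed; the empty subset scores as the
cross-validated majority-category rate, which makes the forward search's
starting point the general-guess baseline.  Steps require strict
improvement (> 10⁻¹²), candidate ties break by column order, and no
subset is evaluated twice.  When stratification is infeasible (a category
with fewer members than folds) plain shuffled folds are used with a
warning.

## Classifiers

All four families are fixed at conventional defaults; none are tuned per
user.

* **naive_bayes** — Gaussian event model per class per feature, variance
  smoothing 10⁻⁹ × max feature variance.  Implemented directly in numpy
  (verified against scikit-learn's `GaussianNB` in the tests) because
  tens of thousands of fits run inside the wrapper searches and estimator
  overhead, not arithmetic, dominated their runtime.
* **c45_tree** — scikit-learn decision tree with entropy splits,
  `min_samples_leaf=2` and cost-complexity pruning `ccp_alpha=0.01`, a
  pruned information-gain tree in the C4.5 family.
* **nb_tree** — bespoke: at each node the single best entropy split is
  found and accepted only if the size-weighted cross-validated accuracy
  of naive-Bayes models in the children beats the node's own naive-Bayes
  cross-validated accuracy.  Default depth limit 2 and minimum leaf size
  8: per-user training sets here are ~56 rows, which cannot support deep
  trees with per-leaf density models.
* **svm** — RBF support vector machine, C = 1.0, kernel scale from the
  median heuristic (γ = 1 / (2 · median squared pairwise training
  distance)).  Multiclass handling is the library's pairwise scheme,
  which for three categories trains the same number of binary machines
  as one-vs-rest.

Single-class training data degrades to a constant predictor with a
warning; an empty wrapper selection deploys the majority-category
predictor.  One model is trained per (user, scale).

## Combination choice

The grid is 4 timeslots × 5 selection methods × 4 families = 80
combinations, evaluated per (user, scale).  Within each (user, scale)
context combinations are ranked by accuracy (rank 1 best, average ranks
on ties, failed combinations get the context's worst rank); a
combination's score is the geometric mean of its ranks — the geometric
mean rather than the raw product so scores are comparable across
different context counts.  The choice is two-staged: per selection
method the rank-product-best (timeslot, family) is fixed, then among the
five method winners the final combination maximises mean accuracy over
the three scales, ties resolving to the smaller timeslot and then method
name order.

## Prospective evaluation

Seven predictions a day, every 2 h from 11:00 to 23:00.  A prediction
succeeds only if all three corrected VAS values fall in their predicted
categories.  Accounting: per-user accuracy = successful/responded;
the cohort figure is the **unweighted mean of per-user accuracies** (the
pooled ratio is also reported and labelled); feedback rate =
responded/issued.  Percentages round half-up to two decimals.  Users
with zero responses are excluded from the mean with a warning.

Benchmarks: per-scale ordinary least squares on the raw VAS values
(prediction = category of the fitted value clipped to [0, 100];
rank-deficient designs fall back to the minimum-norm solution with a
warning), and the general guess, interpreted as the user's most frequent
training category per scale, ties resolving to the lower category.

## The synthetic cohort

The generator emulates the study conditions: 14 training days with 4
tags/day at jittered times in fixed daily slots at least 3 h apart, then
5 evaluation days with reports at the seven 2-hourly prediction times,
each present with probability `response_rate` (default 0.98).

Usage is a pair of marked Poisson processes over the waking day
(08:00–23:00): calls at a per-user rate of 2–5/day (45% outgoing, 40%
answered incoming, 15% missed; log-normal ring and talk durations) and
screen bouts at 12–20/day, each bout 1–3 back-to-back app sessions drawn
from a per-user Dirichlet preference over the app catalog with log-normal
lengths.  These are the simplest processes that give all four feature
statistics non-degenerate distributions; they are conventions, not
estimates from any real cohort.  Event durations are rounded to whole
sampling periods so the emitted sample stream determines the true events
exactly, making exact round-trip checks possible.

The planted dependence acts over a 2-hour window: screen-time total and
count plus one app's total duration are computed per tag from the true
events, z-scored within user, and combined with per-scale weights of one
common sign (heavier usage consistently raises or lowers an emotion; the
planted features are positively correlated, and mixed signs would cancel
marginally, making the coupling undetectable by per-feature tests).  The
combined score is normalized to unit variance so that `effect_size` is
exactly the latent signal sd in VAS units; the latent value is
`50 + effect_size · score`, perturbed by Gaussian noise of sd `noise_sd`,
rounded and clipped to 0–100.  `effect_size = 0` gives tags independent
of usage.

Three regimes are used throughout the tests: the defaults
(`effect_size=25, noise_sd=8`, moderate coupling), a strong-coupling
regime for parameter-recovery checks (`effect_size=40, noise_sd=3`), and
the null (`effect_size=0`).  One master seed drives everything; per-user
substreams are derived from the user id, so users are independent and
insensitive to simulation order.

What the generator does **not** emulate: circadian or weekday structure
in usage, behavioural drift over the study, autocorrelated emotions,
notification-compliance psychology, or multi-device users.  Passing
tests therefore demonstrate that the pipeline recovers a planted
stationary linear coupling — not that real emotions are predictable at
any particular accuracy.

## Problem sizes and numerical conventions

Replicated checks use cohorts of 10 users (the recovery and null
properties run 20 and 2 replicates respectively) and the full
80-combination grid is exercised on one user; these sizes make the whole
suite run in a few minutes while leaving the statistics well-powered.
Monte-Carlo tolerances are derived from the corresponding binomial or
correlation null (3σ bands, inflated for within-user correlation where
applicable) and are stated next to each test.  Determinism contracts:
identical seeds reproduce byte-identical fixture files and summary
tables; fold assignment, tie-breaks (column order for features, smaller
timeslot then name order for combinations, lower category for guess
ties) and column ordering are all fixed.

## Known limitations

* The two-level contrast groupings and the equal-thirds category cuts
  are reasonable fixed conventions; other partitions would change which
  features the filters keep.
* The homoscedastic filter's deletion semantics keep the *least*
  class-separating features by construction; it exists as a specified
  alternative, and under planted signal it is expected to lose to the
  other methods in the rank product — which the selection stage then
  reflects.
* The t-test filter's minimum-5 fill forces features into the model even
  under the null, where it measurably underperforms the majority guess;
  the wrapper searches do not share this behaviour (their empty-set
  score *is* the majority baseline).
* OLS on raw VAS can beat naive Bayes on strongly coupled synthetic
  data, because the generative model is itself linear; this is a feature
  of the synthetic regime, not a statement about real cohorts.
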