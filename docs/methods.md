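# Methods

This note documents the model, the conventions and the design choices
behind the package, and what its synthetic-data validation does and
does not establish.

## Data model

A dataset is a schema of typed predictive attributes (numeric or
nominal) plus instances with an always-present class label.  Missing
cells are first-class: `None` at the instance level, NaN / code −1 in
the columnar arrays.  CSV columns are inferred numeric iff every
non-missing cell parses as a number, otherwise nominal with categories
in first-appearance order; ARFF kinds come from the declarations.  The
category order is load-bearing — it is the deterministic tie-break for
prototype modes — so writers preserve it.  `"?"` and the empty string
are the only missing markers (CSV); numeric cells are written with
`repr` so round trips are exact.

The imbalance ratio is majority/minority class count (global max/min
for multiclass).  Its 2-decimal display **truncates** rather than
rounds (187/175 = 1.0686 → "1.06"), matching the convention of the
published dataset tables this package mirrors; the computation is done
in integer arithmetic so no floating-point edge case can flip a digit.

## HEOM

Per-attribute distances: 1 if either value is missing; 0/1 overlap for
nominals; `|a−b|/range` for numerics with the range taken from the
*construction* data only.  Zero-range numeric attributes compare by
equality (avoids division by zero while preserving discrimination);
out-of-range test values are clipped so each term stays in [0, 1] and
the global bound `sqrt(m)` holds.  Aggregation is root-sum-of-squares
(the Wilson–Martinez form), unnormalised by attribute count.  The
missing→1 rule is the mechanism by which classification works on
incomplete instances without any imputation.

Dissimilarities are a named strategy ("heom" default); alternative
metrics can be registered without touching the classifier.

## The classifier

Training splits the data by stratified hold-out (default 0.7
construction / 0.3 validation, round-half-up per class with both sides
kept non-empty for classes of ≥2 instances; singleton classes go to
construction).  Defaults: bag_size 5, 10 generations, 5 clones per
prototype, mutation rate 0.1, patience 3.  These magnitudes mirror the
standard defaults of comparable immune classifiers (e.g. a clonal
factor of 0.1 and 10 generations in CLONALG); no per-dataset tuning is
performed anywhere in the package.

Design choices where the procedure was genuinely open:

* **Bag construction** draws `max(1, ⌈n_c/bag_size⌉)` seeds per class
  without replacement and assigns the rest by nearest seed (ties to
  the lowest seed index).  This is deterministic, class-pure and
  O(n·b), in keeping with the method's low-complexity intent.
* **Merging** uses the mean/mode of *observed* member values only.
  Substituting missing member values by the attribute mean before
  averaging is arithmetically the same thing; crucially, an attribute
  observed in no member **stays missing** in the prototype.  This
  keeps singleton-bag prototypes identical to their instance, which in
  turn makes the degenerate configuration (bag_size 1, no
  generations) *exactly* 1-NN/HEOM over the construction set — the
  package's strongest correctness oracle.  A class- or dataset-level
  fallback imputation was considered and rejected: it would inject
  artificial values into prototypes and break that equivalence.
* **Movement and clonal acceptance** are strict-improvement-only on
  the *validation* balanced accuracy (the anti-overfitting intent of
  the clonal phase dictates optimizing on held-out data, not on the
  construction part).  Strictness plus elitist best-so-far tracking
  guarantees a non-decreasing fitness trajectory — a property the test
  suite asserts over every pass of dozens of seeded runs.
* **Moves that would empty their source bag are not candidates**, so
  every initial bag keeps ≥1 member and every class keeps ≥1
  prototype.
* **Prediction ties** (exact equal distances, common when distances
  are driven by nominal/missing contributions) go to the class with
  the larger training count, then the lower class index.  The 1-NN
  baseline instead breaks ties by dataset order; equivalence tests
  therefore assert exact prediction equality where the nearest
  distance is unique and tie-class membership otherwise.

Reproducibility: a single root seed is expanded through numpy seed
sequences into independent streams for the hold-out split and the
evolutionary passes; (data, params, seed) determine the serialized
memory byte-for-byte.  The memory JSON stores schema, classes, training
class counts, ranges, parameters (seed included), prototypes with
explicit missing markers, the validation partition and the fitness, so
a stored model can re-derive its own fitness exactly.

## Evaluation and comparison

Balanced accuracy is the mean of per-class recalls over classes with at
least one true instance (`k_effective`), so no recall is ever 0/0; with
equal class supports it coincides with plain accuracy (property-tested).

The Wilcoxon signed-rank test uses: average ranks over all
|differences| including zeros; zero ranks split evenly between R+ and
R− (one zero pair dropped, n reduced by 1, if their count is odd);
two-sided p from the continuity-corrected normal approximation applied
to the smaller rank sum.  This is the unique standard-family variant
that reproduces the published comparison table's p-values (0.004317 at
R−=0, 0.005922 at R−=1, n=10) to printed precision; the exact-
distribution p (0.00195 at R−=0) does not match that table.  n < 5 is
rejected; all-zero differences give the degenerate p=1 result.

For small n the accept/reject decision of this approximation is checked
against an exact enumeration oracle over all 2ⁿ sign assignments.  The
oracle uses the **mid-p** two-sided convention, 2·(P(W<w) + ½P(W=w)):
continuity-corrected normal tails are the large-n approximation of
mid-p, and decision agreement at α=0.05 holds for *every* no-tie (n, W)
with 5 ≤ n ≤ 12 under this convention (verified exhaustively), whereas
the conventional doubled-tail exact p disagrees at a handful of
boundary statistics (e.g. n=5, W=0).

`best_count` counts rows where the focal algorithm ties-or-beats every
competitor; ties count as best, matching how published score tables
bold shared maxima.  Three rows of the published comparison table
(C4.5, ALVOT, NAC) cannot be reproduced from the rounded printed
scores — recomputing C4.5 from them gives R+=45.5/R−=9.5 against a
printed 49/6 — presumably because the original test ran on unrounded
scores; these rows are excluded from the reproduction checks, which
cover the five sign-consistent comparisons.

## Synthetic data

The generator emulates the character of the benchmark clinical tables:
mixed attribute types, 2–3 classes, imbalance ratios from 1 to ~6,
optional MCAR missingness.  Numeric attributes are class-conditional
unit-variance Gaussians with means offset by `class_separation` σ;
nominal attributes put probability mass `1/C + (1 − 1/C)·min(1,
separation/4)` on a class-preferred category — exactly uniform (zero
signal) at separation 0, so the no-signal null calibrates to balanced
accuracy ≈ 0.5.  One instance per class is guaranteed; the remaining
labels are multinomial, so the realized imbalance ratio carries
binomial sampling noise.  Missingness is MCAR only — the minimal
mechanism that exercises the HEOM missing rule and the observed-only
merging; MAR/MNAR mechanisms, attribute correlations and label noise
are deliberately out of scope.

Consequently, passing the synthetic validation shows the
implementation is faithful (oracle equivalence, elitism, metric axioms,
signal recovery and calibration) but not that the classifier attains
any particular accuracy on real clinical data, whose missingness is
rarely MCAR and whose attributes are correlated.

## Problem sizes and numerical notes

The validation suite uses datasets of 20–60 instances for the oracle
and elitism properties, n=300 for the recovery check (10 seeds,
separation 3, 10% missing), 1000 random pairs for the metric axioms
(agreement ≤ 1e-12 with an independently coded brute force) and 300–500
random paired samples for the Wilcoxon oracle; these sizes make the
properties sharp while keeping the full run in minutes on one core.
Distance ties are compared by exact float equality (deterministic, as
both sides come from the same arithmetic); candidate moves are
evaluated by patching only the two affected columns of the cached
validation-distance matrix, which makes a movement pass O(n·b) distance
updates rather than a full re-evaluation.

## Known limitations

* Nominal categories that all look numeric are re-inferred as numeric
  on a CSV round trip; use ARFF when kinds must be pinned.
* The movement pass evaluates single-instance moves only; coordinated
  multi-instance rearrangements are out of reach of one pass (they can
  still be realised across passes).
* No parameter search is provided by design; all defaults are fixed
  once and used everywhere.
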