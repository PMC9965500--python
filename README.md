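# aisac

Immune-inspired prototype classification of **mixed and incomplete
tabular data**, built for the kind of clinical datasets where numeric
measurements sit next to categorical findings and cells are routinely
missing — and where imputing or dropping those cells before
classification distorts the data.

The package implements **AISAC-MMD** (Artificial Immune System for
Associative Classification of Mixed and Missing Data), a prototype
generation classifier that handles such data natively, together with the
full experimental apparatus around it: CSV/ARFF dataset I/O and
profiling, the HEOM dissimilarity, balanced-accuracy evaluation, a
1-NN/HEOM reference baseline, Wilcoxon signed-rank comparison of
classifiers, and a synthetic mixed/incomplete data generator.

## The method

**Dissimilarity.** Instances are compared with the Heterogeneous
Euclidean-Overlap Metric.  Per attribute *a*:

```
d_a(x, y) = 1                         if x or y is missing
          = [x ≠ y]                   if a is nominal
          = min(|x − y| / range_a, 1) if a is numeric
```

with `range_a = max_a − min_a` observed on training data only, and
`HEOM(x, y) = sqrt(Σ_a d_a²) ∈ [0, sqrt(m)]`.  The missing rule is what
lets the classifier consume incomplete instances without imputation.

**Training** mimics an adaptive immune response.  The training set is
split by stratified hold-out into a construction and a validation part;
then:

1. *Bagging* — each class is partitioned into `max(1, ⌈n_c/bag_size⌉)`
   class-pure clusters around seeded leaders (nearest-seed assignment).
2. *Merging* — each bag collapses into one prototype: attribute-wise
   mean (numeric) / mode (nominal) over the members' **observed**
   values; attributes missing in every member stay missing, and the
   original instances are never modified.
3. *Movement* — instances are tentatively reassigned between same-class
   bags; a move is kept only if it strictly improves the validation
   **balanced accuracy** `BA = (1/k) Σ_i S_i` (mean per-class recall
   `S_i`) of the 1-nearest-prototype classifier.
4. *Clonal selection* — each prototype spawns mutated clones (Gaussian
   noise scaled to the training range for numerics, random category
   flips for nominals); a prototype is replaced by its best clone only
   on strict validation improvement, counteracting overfitting.

Phases 3–4 alternate with early stopping under an elitist
accept-only-if-better rule, so validation fitness is non-decreasing.
Classification returns the class of the HEOM-nearest prototype (distance
ties go to the class with more training instances, then the lower class
index).  Everything is deterministic given (data, parameters, seed).

**Comparison tooling.**  Classifiers are compared over paired
per-dataset balanced accuracies with the Wilcoxon signed-rank test:
average ranks over all |differences| (zeros split evenly between R+ and
R−, one zero dropped if their count is odd), two-sided p-value from the
continuity-corrected normal approximation
`p = 2·Φ((min(R+,R−) − 0.5 − n(n+1)/4)/σ)`, `σ = sqrt(n(n+1)(2n+1)/24)`.

## Worked example

`examples/02_train_and_classify.py` trains on a synthetic imbalanced
binary dataset (n = 300, 70/30 classes, 4 numeric + 3 nominal
attributes, 10 % missing cells, class separation 3σ) and evaluates on a
fresh draw:

```
training instances : 300
prototypes stored  : 43
validation fitness : 0.9921
held-out balanced accuracy: 0.9595
per-class recall          : class0=0.986, class1=0.933
first test instance       -> class0
an all-missing instance   -> class0 (equidistant from every prototype; the tie goes to the majority class)
```

The memory compresses 300 instances into 43 prototypes while keeping
held-out balanced accuracy near 0.96; the all-missing instance shows the
classifier is total over any missingness pattern.  The other scripts in
`examples/` cover generation/profiling, HEOM arithmetic, and the
published-table comparison (`04_compare_published_scores.py` prints the
R+/R−/p table reproduced below under *Reproducing the results*).

The same workflows are available from the shell:

```sh
aisac synth -o data.csv --seed 7 --n-instances 300 --class-separation 3
aisac fit data.csv -o model.json --seed 7
aisac predict model.json data.csv -o predictions.csv
aisac evaluate model.json data.csv
aisac compare scores.csv --focal AISAC-MMD
```

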