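"""Published benchmark results for AISAC-MMD and its competitors.

The study that introduced AISAC-MMD evaluated it on ten public
cancer-related tabular datasets against five classifiers that handle
mixed/incomplete data (ALVOT, C4.5, NAC, Naïve Bayes, 1-NN) and three
immune-inspired classifiers (AIRS1, CLONALG, Immunos1), reporting
balanced accuracies and a Wilcoxon signed-rank comparison.  The printed
score tables are reproduced here as inputs for the comparison tooling —
they are *data*, not anything this package recomputes on the real
datasets (which would require external downloads and unspecified
hyperparameters).

``MIXED_CLASSIFIER_SCORES`` / ``IMMUNE_CLASSIFIER_SCORES`` are
dataset-by-algorithm balanced accuracies; ``DATASET_CLASS_COUNTS`` gives
published per-class instance counts for the two datasets whose counts
appear explicitly.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "FOCAL",
    "DATASETS",
    "MIXED_CLASSIFIER_SCORES",
    "IMMUNE_CLASSIFIER_SCORES",
    "DATASET_CLASS_COUNTS",
    "mixed_scores",
    "immune_scores",
]

FOCAL = "AISAC-MMD"

DATASETS = (
    "BCDR", "BCWO", "BCSEER", "BCWD", "BCWP",
    "LCDS", "MMDS", "BCDS", "HSDS", "TSDS",
)

# balanced accuracies: classifiers that natively handle mixed/missing data
MIXED_CLASSIFIER_SCORES = {
    "ALVOT":       (0.770, 0.941, 0.834, 0.934, 0.563, 0.542, 0.789, 0.728, 0.748, 0.728),
    "C4.5":        (0.749, 0.951, 1.000, 0.931, 0.727, 0.469, 0.823, 0.741, 0.703, 0.845),
    "NAC":         (0.678, 0.975, 0.908, 0.894, 0.699, 0.450, 0.806, 0.731, 0.733, 0.774),
    "Naive Bayes": (0.727, 0.960, 0.972, 0.930, 0.667, 0.594, 0.778, 0.727, 0.748, 0.745),
    "NN":          (0.729, 0.953, 0.984, 0.960, 0.707, 0.531, 0.752, 0.682, 0.660, 0.760),
    FOCAL:         (0.784, 0.969, 1.000, 0.965, 0.767, 0.688, 0.797, 0.731, 0.765, 0.845),
}

# balanced accuracies: immune-inspired classifiers
IMMUNE_CLASSIFIER_SCORES = {
    "AIRS1":    (0.732, 0.967, 0.945, 0.938, 0.641, 0.531, 0.634, 0.675, 0.637, 0.774),
    "CLONALG":  (0.577, 0.941, 0.965, 0.889, 0.742, 0.469, 0.700, 0.671, 0.732, 0.745),
    "Immunos1": (0.561, 0.847, 0.954, 0.905, 0.566, 0.563, 0.743, 0.734, 0.568, 0.760),
    FOCAL:      (0.784, 0.969, 1.000, 0.965, 0.767, 0.688, 0.797, 0.731, 0.765, 0.845),
}

# published per-class counts (majority, minority)
DATASET_CLASS_COUNTS = {
    "BCDR": (187, 175),   # benign vs malignant findings
    "MMDS": (516, 445),   # benign vs malignant masses
}


def mixed_scores() -> pd.DataFrame:
    """Score table for the mixed/missing-capable classifier comparison."""
    return pd.DataFrame(MIXED_CLASSIFIER_SCORES, index=list(DATASETS))


def immune_scores() -> pd.DataFrame:
    """Score table for the immune-classifier comparison."""
    return pd.DataFrame(IMMUNE_CLASSIFIER_SCORES, index=list(DATASETS))
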