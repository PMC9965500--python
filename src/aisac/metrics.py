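"""Evaluation machinery: balanced accuracy, a 1-NN/HEOM reference
baseline, and the Wilcoxon signed-rank comparison of classifiers.

Balanced accuracy is the macro-average of per-class recalls,
``BA = (1/k) * sum_i S_i`` with ``S_i`` the recall of class ``i``; under
class imbalance it avoids the majority-class bias of plain accuracy.
Classes with no true instance in the evaluated sample are excluded from
``k`` (``k_effective``) so no recall is ever 0/0.

The Wilcoxon signed-rank test compares two classifiers over paired
per-dataset scores.  Conventions, chosen to match the comparison tables
standard in this literature:

* all ``|d_i|`` (zero differences included) receive average ranks;
* ranks of zero differences are split evenly between R+ and R- (the
  Demšar convention); if their count is odd one zero pair is dropped and
  ``n`` reduced by 1;
* two-sided p from the continuity-corrected normal approximation,
  ``p = 2 * Phi((min(R+, R-) - 0.5 - n(n+1)/4) / sigma)`` with
  ``sigma = sqrt(n(n+1)(2n+1)/24)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data import MixedDataset
from .exceptions import ValidationError
from .heom import RangeTable, heom

__all__ = [
    "ConfusionMatrix",
    "BalancedAccuracyResult",
    "WilcoxonResult",
    "confusion_matrix",
    "balanced_accuracy",
    "nn_baseline",
    "nn_baseline_batch",
    "wilcoxon_signed_rank",
    "best_count",
    "comparison_report",
    "format_comparison_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k contingency table; rows = true class, columns = predicted."""

    classes: tuple
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    truth: Sequence, predicted: Sequence, classes: Sequence
) -> ConfusionMatrix:
    """Count predictions per (true, predicted) class pair."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValidationError("truth and predicted must have equal length")
    if not truth:
        raise ValidationError("cannot build a confusion matrix from no labels")
    classes = tuple(classes)
    code = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in code or p not in code:
            raise ValidationError(f"label outside class list: {t!r} / {p!r}")
        counts[code[t], code[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass(frozen=True)
class BalancedAccuracyResult:
    """Macro-averaged recall with its per-class breakdown."""

    per_class_recall: dict
    k_effective: int
    value: float


def balanced_accuracy(cm: ConfusionMatrix) -> BalancedAccuracyResult:
    """Mean per-class recall over classes with at least one true instance."""
    row_sums = cm.counts.sum(axis=1)
    if not (row_sums > 0).any():
        raise ValidationError("confusion matrix has no true instances")
    recalls = {}
    for i, c in enumerate(cm.classes):
        if row_sums[i] > 0:
            recalls[c] = float(cm.counts[i, i] / row_sums[i])
    return BalancedAccuracyResult(
        per_class_recall=recalls,
        k_effective=len(recalls),
        value=float(sum(recalls.values()) / len(recalls)),
    )


def nn_baseline(train: MixedDataset, x, ranges: RangeTable):
    """1-nearest-neighbour label under HEOM; ties go to the earliest
    training instance in dataset order.

    Serves as the independent reference classifier: with singleton bags
    and no refinement the immune classifier must coincide with it.
    """
    if train.n_instances == 0:
        raise ValidationError("empty training set")
    xv = x.values if hasattr(x, "values") and hasattr(x, "label") else x
    best_d = math.inf
    best_i = 0
    for i in range(train.n_instances):
        d = heom(xv, train.row_values(i), train.schema, ranges)
        if d < best_d:
            best_d = d
            best_i = i
    return train.classes[train.y[best_i]]


def nn_baseline_batch(
    train: MixedDataset, test: MixedDataset, ranges: RangeTable
) -> list:
    """Apply :func:`nn_baseline` to every row of ``test``."""
    return [
        nn_baseline(train, test.row_values(i), ranges)
        for i in range(test.n_instances)
    ]


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of a paired Wilcoxon signed-rank comparison."""

    n: int
    r_plus: float
    r_minus: float
    p_value: float
    alpha: float
    reject_h0: bool

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "r_plus": self.r_plus,
            "r_minus": self.r_minus,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "decision": "Reject H0" if self.reject_h0 else "Retain H0",
        }


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test on ``d = a - b``.

    R+ sums the ranks of positive differences (first sample better), R-
    of negative ones; see the module docstring for the zero and tie
    conventions.  Requires ``n >= 5`` — below that the normal
    approximation is unreliable.  If every difference is zero the result
    is degenerate: ``p = 1``, no rejection, rank mass split evenly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length vectors")
    n = len(a)
    if n < 5:
        raise ValidationError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0.0):
        half = n * (n + 1) / 4
        return WilcoxonResult(n, half, half, 1.0, alpha, False)
    zeros = np.flatnonzero(d == 0.0)
    if len(zeros) % 2 == 1:
        d = np.delete(d, zeros[0])
        n -= 1
    ranks = rankdata(np.abs(d))
    zero_mass = ranks[d == 0.0].sum()
    r_plus = float(ranks[d > 0.0].sum() + zero_mass / 2)
    r_minus = float(ranks[d < 0.0].sum() + zero_mass / 2)
    w = min(r_plus, r_minus)
    mu = n * (n + 1) / 4
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    p = float(min(1.0, 2.0 * norm.cdf((w - 0.5 - mu) / sigma)))
    return WilcoxonResult(n, r_plus, r_minus, p, alpha, p < alpha)


def best_count(table: pd.DataFrame, focal: str) -> int:
    """Rows of a dataset-by-algorithm score table where the focal
    algorithm ties or beats every other column.

    Ties count as best, matching how comparison tables bold shared
    maxima.
    """
    if focal not in table.columns:
        raise ValidationError(f"focal column {focal!r} not in table")
    if len(table) == 0:
        raise ValidationError("score table has no rows")
    row_max = table.max(axis=1)
    return int((table[focal] >= row_max).sum())


def comparison_report(
    table: pd.DataFrame, focal: str, alpha: float = 0.05
) -> dict:
    """Wilcoxon comparison of the focal algorithm against every other
    column of a dataset-by-algorithm score table.

    Returns a JSON-ready dict with one entry per competitor plus the
    focal best count.
    """
    if focal not in table.columns:
        raise ValidationError(f"focal column {focal!r} not in table")
    comparisons = []
    for col in table.columns:
        if col == focal:
            continue
        res = wilcoxon_signed_rank(table[focal], table[col], alpha=alpha)
        comparisons.append({"algorithm": str(col), **res.to_json_dict()})
    return {
        "focal": focal,
        "alpha": alpha,
        "n_datasets": int(len(table)),
        "best_count": best_count(table, focal),
        "comparisons": comparisons,
    }


def format_comparison_table(report: dict) -> str:
    """Aligned-text rendering of :func:`comparison_report` output."""
    header = f"{report['focal']} vs.".ljust(16)
    lines = [f"{header}  {'R+':>6}  {'R-':>6}  {'p-Value':>10}  Decision"]
    for row in report["comparisons"]:
        lines.append(
            f"{row['algorithm']:<16}  {row['r_plus']:>6.1f}  "
            f"{row['r_minus']:>6.1f}  {row['p_value']:>10.6f}  "
            f"{row['decision']}"
        )
    return "\n".join(lines)
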