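"""Heterogeneous Euclidean-Overlap Metric (HEOM) for mixed, incomplete data.

HEOM compares two instances attribute by attribute:

* numeric attribute: ``|a - b| / range``, where the range is ``max - min``
  observed on the *training construction* data only; values outside the
  training range are clipped so the per-attribute distance stays in [0, 1],
  and a zero-range attribute compares by equality (0 or 1);
* nominal attribute: the overlap metric — 0 if equal, 1 otherwise;
* if either value is missing the per-attribute distance is 1.

The per-attribute distances ``d_a`` aggregate as ``sqrt(sum_a d_a**2)``
(the Wilson–Martinez root-sum-of-squares form), bounded by ``sqrt(m)`` for
``m`` attributes.  The missing rule is what lets a nearest-prototype
classifier operate on incomplete data without imputing anything.

Dissimilarities are pluggable strategies; ``"heom"`` is the default and
currently the only built-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import AttributeSchema, MixedDataset
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "RangeTable",
    "attribute_distance",
    "heom",
    "pairwise_heom",
    "HeomMetric",
    "get_dissimilarity",
    "DISSIMILARITIES",
]


@dataclass(frozen=True)
class RangeTable:
    """Per-attribute training statistics needed by HEOM.

    Built from training (construction) data only — never from test
    instances — so test-time values falling outside ``[min, max]`` are
    clipped rather than re-scaled.

    ``mins``/``maxs``/``ranges`` are aligned to the numeric columns of the
    schema; ``observed`` counts non-missing values per predictive
    attribute (in attribute order).
    """

    numeric_attr_indices: tuple[int, ...]
    mins: np.ndarray
    maxs: np.ndarray
    ranges: np.ndarray
    observed: np.ndarray

    @classmethod
    def from_dataset(cls, dataset: MixedDataset) -> "RangeTable":
        import warnings

        X = dataset.X_num
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mins = np.nanmin(X, axis=0) if X.size else np.zeros(X.shape[1])
            maxs = np.nanmax(X, axis=0) if X.size else np.zeros(X.shape[1])
        # a column with no observed value gets a degenerate zero range
        mins = np.where(np.isnan(mins), 0.0, mins)
        maxs = np.where(np.isnan(maxs), 0.0, maxs)
        observed = np.zeros(dataset.n_attributes, dtype=np.int64)
        for j, a in enumerate(dataset.numeric_attr_indices):
            observed[a] = np.count_nonzero(~np.isnan(X[:, j]))
        for j, a in enumerate(dataset.nominal_attr_indices):
            observed[a] = np.count_nonzero(dataset.X_nom[:, j] >= 0)
        return cls(
            numeric_attr_indices=dataset.numeric_attr_indices,
            mins=mins,
            maxs=maxs,
            ranges=maxs - mins,
            observed=observed,
        )

    def numeric_column(self, attr_index: int) -> int:
        try:
            return self.numeric_attr_indices.index(attr_index)
        except ValueError:
            raise ValidationError(
                f"attribute index {attr_index} is not numeric in this table"
            ) from None

    def to_json_dict(self) -> dict:
        return {
            "numeric_attr_indices": list(self.numeric_attr_indices),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
            "observed": [int(v) for v in self.observed],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RangeTable":
        mins = np.asarray(d["mins"], dtype=float)
        maxs = np.asarray(d["maxs"], dtype=float)
        return cls(
            numeric_attr_indices=tuple(d["numeric_attr_indices"]),
            mins=mins,
            maxs=maxs,
            ranges=maxs - mins,
            observed=np.asarray(d["observed"], dtype=np.int64),
        )


def attribute_distance(
    a, b, schema_attr: AttributeSchema, ranges: RangeTable
) -> float:
    """HEOM distance contribution of one attribute; always in [0, 1]."""
    if a is None or b is None:
        return 1.0
    if schema_attr.is_numeric:
        r = float(ranges.ranges[ranges.numeric_column(schema_attr.index)])
        a = float(a)
        b = float(b)
        if r == 0.0:
            return 0.0 if a == b else 1.0
        return min(abs(a - b) / r, 1.0)
    for v in (a, b):
        if v not in schema_attr.categories:
            raise ValidationError(
                f"value {v!r} not among categories of {schema_attr.name!r}"
            )
    return 0.0 if a == b else 1.0


def heom(
    x: Sequence,
    y: Sequence,
    schema: Sequence[AttributeSchema],
    ranges: RangeTable,
) -> float:
    """HEOM dissimilarity between two instances' predictive values.

    Accepts raw value sequences (``None`` = missing) or :class:`Instance`
    objects; returns a value in ``[0, sqrt(m)]``.
    """
    xv = x.values if hasattr(x, "values") and hasattr(x, "label") else x
    yv = y.values if hasattr(y, "values") and hasattr(y, "label") else y
    if len(xv) != len(schema) or len(yv) != len(schema):
        raise ValidationError(
            "instance length does not match schema "
            f"({len(xv)}, {len(yv)} vs {len(schema)})"
        )
    total = 0.0
    for attr, a, b in zip(schema, xv, yv):
        d = attribute_distance(a, b, attr, ranges)
        total += d * d
    return math.sqrt(total)


def pairwise_heom(
    A_num: np.ndarray,
    A_nom: np.ndarray,
    B_num: np.ndarray,
    B_nom: np.ndarray,
    ranges: RangeTable,
) -> np.ndarray:
    """Vectorised HEOM matrix between two row blocks.

    ``*_num`` are float matrices (NaN = missing) and ``*_nom`` integer code
    matrices (-1 = missing), as stored by :class:`MixedDataset`.  Returns
    an ``(n_A, n_B)`` matrix.
    """
    nA = A_num.shape[0]
    nB = B_num.shape[0]
    sq = np.zeros((nA, nB))
    if A_num.shape[1]:
        a = A_num[:, None, :]
        b = B_num[None, :, :]
        r = ranges.ranges
        safe_r = np.where(r > 0.0, r, 1.0)
        with np.errstate(invalid="ignore"):
            d = np.abs(a - b) / safe_r
            d = np.minimum(d, 1.0)
            zero_r = r == 0.0
            if zero_r.any():
                d = np.where(zero_r & (a == b), 0.0, np.where(zero_r, 1.0, d))
            d = np.where(np.isnan(a) | np.isnan(b), 1.0, d)
        sq += (d * d).sum(axis=2)
    if A_nom.shape[1]:
        a = A_nom[:, None, :]
        b = B_nom[None, :, :]
        d = ((a != b) | (a < 0) | (b < 0)).astype(float)
        sq += d.sum(axis=2)
    return np.sqrt(sq)


class HeomMetric:
    """HEOM bound to a schema and a training range table."""

    name = "heom"

    def __init__(
        self, schema: Sequence[AttributeSchema], ranges: RangeTable
    ) -> None:
        self.schema = tuple(schema)
        self.ranges = ranges

    def __call__(self, x, y) -> float:
        return heom(x, y, self.schema, self.ranges)

    def pairwise(self, A_num, A_nom, B_num, B_nom) -> np.ndarray:
        return pairwise_heom(A_num, A_nom, B_num, B_nom, self.ranges)


#: Registry of named dissimilarity strategies.
DISSIMILARITIES: dict[str, type] = {"heom": HeomMetric}


def get_dissimilarity(name: str) -> type:
    try:
        return DISSIMILARITIES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown dissimilarity {name!r}; available: "
            f"{sorted(DISSIMILARITIES)}"
        ) from None
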