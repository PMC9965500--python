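"""Mixed-type, possibly incomplete tabular datasets.

Clinical tabular data routinely combines numeric measurements with
categorical (nominal) findings, and cells are frequently missing.  This
module defines the in-memory representation used throughout the package —
a schema of typed attributes plus columnar value arrays with explicit
missing markers — together with CSV/ARFF readers and writers, dataset
profiling (class counts, imbalance ratio) and seeded stratified hold-out
splitting.

Missing cells are represented as ``None`` at the instance level; internally
numeric columns use NaN and nominal columns use the code ``-1``.  Class
labels are never missing: rows without a label are rejected at load time.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .exceptions import ConfigurationError, ParseError, ValidationError

__all__ = [
    "AttributeSchema",
    "Instance",
    "MixedDataset",
    "DatasetProfile",
    "MISSING_TOKENS",
    "read_dataset",
    "write_dataset",
    "profile",
    "stratified_holdout",
    "truncate_ratio",
]

#: Cell tokens interpreted as a missing value in CSV files.
MISSING_TOKENS = ("?", "")

NUMERIC = "numeric"
NOMINAL = "nominal"


@dataclass(frozen=True)
class AttributeSchema:
    """Declaration of one predictive attribute.

    Parameters
    ----------
    name
        Attribute name, unique within a dataset.
    kind
        ``"numeric"`` or ``"nominal"``.
    index
        0-based position among the predictive attributes.
    categories
        Admissible category labels for nominal attributes, in a fixed
        order (declaration order for ARFF, first appearance for CSV).
        The order is meaningful: it is the deterministic tie-break used
        when computing prototype modes.  Empty for numeric attributes.
    """

    name: str
    kind: str
    index: int
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, NOMINAL):
            raise ValidationError(f"unknown attribute kind {self.kind!r}")
        if self.kind == NOMINAL:
            if len(self.categories) < 1:
                raise ValidationError(
                    f"nominal attribute {self.name!r} needs >=1 category"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ValidationError(
                    f"duplicate categories in attribute {self.name!r}"
                )
        elif self.categories:
            raise ValidationError(
                f"numeric attribute {self.name!r} cannot declare categories"
            )

    @property
    def is_numeric(self) -> bool:
        return self.kind == NUMERIC


class Instance(NamedTuple):
    """One row: predictive values (``None`` = missing) and its class label."""

    values: tuple
    label: str


class MixedDataset:
    """A schema-typed collection of mixed/incomplete instances.

    Values are stored columnar: numeric attributes in a float matrix with
    NaN for missing, nominal attributes as integer category codes with -1
    for missing.  Instances are exposed row-wise via :meth:`instance` /
    iteration, with ``None`` marking missing cells.
    """

    def __init__(
        self,
        schema: Sequence[AttributeSchema],
        classes: Sequence[str],
        X_num: np.ndarray,
        X_nom: np.ndarray,
        y: np.ndarray,
        class_name: str = "class",
    ) -> None:
        self.schema = tuple(schema)
        self.classes = tuple(classes)
        self.class_name = class_name
        self.X_num = np.asarray(X_num, dtype=float)
        self.X_nom = np.asarray(X_nom, dtype=np.int32)
        self.y = np.asarray(y, dtype=np.int32)
        self._validate()
        self.numeric_attr_indices = tuple(
            a.index for a in self.schema if a.is_numeric
        )
        self.nominal_attr_indices = tuple(
            a.index for a in self.schema if not a.is_numeric
        )

    def _validate(self) -> None:
        names = [a.name for a in self.schema]
        if len(set(names)) != len(names):
            raise ValidationError("attribute names must be unique")
        if [a.index for a in self.schema] != list(range(len(self.schema))):
            raise ValidationError("attribute indices must be contiguous from 0")
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("duplicate class labels")
        n = len(self.y)
        m_num = sum(a.is_numeric for a in self.schema)
        m_nom = len(self.schema) - m_num
        if self.X_num.shape != (n, m_num) or self.X_nom.shape != (n, m_nom):
            raise ValidationError("value array shapes inconsistent with schema")
        if n and (self.y.min() < 0 or self.y.max() >= len(self.classes)):
            raise ValidationError("class code out of range")
        nom_schema = [a for a in self.schema if not a.is_numeric]
        for j, attr in enumerate(nom_schema):
            col = self.X_nom[:, j]
            if n and col.max(initial=-1) >= len(attr.categories):
                raise ValidationError(
                    f"category code out of range for attribute {attr.name!r}"
                )

    # -- construction -------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        schema: Sequence[AttributeSchema],
        rows: Iterable[Sequence],
        labels: Sequence[str],
        classes: Sequence[str] | None = None,
        class_name: str = "class",
    ) -> "MixedDataset":
        """Build a dataset from row-wise values (``None`` = missing)."""
        schema = tuple(schema)
        rows = [tuple(r) for r in rows]
        labels = list(labels)
        if len(rows) != len(labels):
            raise ValidationError("rows and labels must have equal length")
        if classes is None:
            classes = list(dict.fromkeys(labels))
        classes = list(classes)
        class_code = {c: i for i, c in enumerate(classes)}
        num_attrs = [a for a in schema if a.is_numeric]
        nom_attrs = [a for a in schema if not a.is_numeric]
        n = len(rows)
        X_num = np.full((n, len(num_attrs)), np.nan)
        X_nom = np.full((n, len(nom_attrs)), -1, dtype=np.int32)
        y = np.empty(n, dtype=np.int32)
        cat_code = [
            {c: k for k, c in enumerate(a.categories)} for a in nom_attrs
        ]
        for i, (row, lab) in enumerate(zip(rows, labels)):
            if len(row) != len(schema):
                raise ValidationError(
                    f"row {i} has {len(row)} values, schema expects {len(schema)}"
                )
            if lab not in class_code:
                raise ValidationError(f"row {i}: unknown class label {lab!r}")
            y[i] = class_code[lab]
            jn = jc = 0
            for attr, v in zip(schema, row):
                if attr.is_numeric:
                    if v is not None:
                        X_num[i, jn] = float(v)
                    jn += 1
                else:
                    if v is not None:
                        try:
                            X_nom[i, jc] = cat_code[jc][v]
                        except KeyError:
                            raise ValidationError(
                                f"row {i}: value {v!r} not among categories "
                                f"of attribute {attr.name!r}"
                            ) from None
                    jc += 1
        return cls(schema, classes, X_num, X_nom, y, class_name=class_name)

    # -- basic accessors ----------------------------------------------

    @property
    def n_instances(self) -> int:
        return len(self.y)

    @property
    def n_attributes(self) -> int:
        return len(self.schema)

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.y, minlength=len(self.classes))
        return {c: int(k) for c, k in zip(self.classes, counts)}

    def has_missing(self) -> bool:
        return bool(np.isnan(self.X_num).any() or (self.X_nom < 0).any())

    def row_values(self, i: int) -> tuple:
        """Predictive values of row ``i`` in attribute order (None = missing)."""
        out = []
        jn = jc = 0
        for attr in self.schema:
            if attr.is_numeric:
                v = self.X_num[i, jn]
                out.append(None if math.isnan(v) else float(v))
                jn += 1
            else:
                c = int(self.X_nom[i, jc])
                out.append(None if c < 0 else attr.categories[c])
                jc += 1
        return tuple(out)

    def instance(self, i: int) -> Instance:
        return Instance(self.row_values(i), self.classes[self.y[i]])

    def __iter__(self) -> Iterator[Instance]:
        return (self.instance(i) for i in range(self.n_instances))

    def __len__(self) -> int:
        return self.n_instances

    def subset(self, indices: Sequence[int]) -> "MixedDataset":
        """Row subset sharing this dataset's schema and class list."""
        idx = np.asarray(indices, dtype=int)
        return MixedDataset(
            self.schema,
            self.classes,
            self.X_num[idx],
            self.X_nom[idx],
            self.y[idx],
            class_name=self.class_name,
        )


# ---------------------------------------------------------------------------
# Reading and writing


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    elif str(path).lower().endswith(".arff"):
        fmt = "arff"
    else:
        fmt = "csv"
    if fmt not in ("csv", "arff"):
        raise ConfigurationError(f"unknown dataset format {fmt!r}")
    return fmt


def _resolve_class_column(header: list[str], class_column: str) -> int:
    if class_column == "last":
        return len(header) - 1
    try:
        return header.index(class_column)
    except ValueError:
        raise ConfigurationError(
            f"class column {class_column!r} not found; columns: {header}"
        ) from None


def read_dataset(
    path, format: str | None = None, class_column: str = "last"
) -> MixedDataset:
    """Read a CSV or ARFF file into a :class:`MixedDataset`.

    CSV files must carry a header row; ``"?"`` and empty cells are missing.
    A predictive column is numeric iff every non-missing cell parses as a
    number, otherwise nominal with categories in first-appearance order.
    ARFF attribute kinds come from the ``@attribute`` declarations.

    ``class_column`` names the decision attribute, or ``"last"`` (the
    default, following the usual repository convention).
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, class_column)
    return _read_arff(path, class_column)


def _read_csv(path, class_column: str) -> MixedDataset:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            table = list(reader)
        except csv.Error as exc:
            raise ParseError(f"{path}: line {reader.line_num}: {exc}") from exc
    if not table:
        raise ParseError(f"{path}: empty file (a header row is required)")
    header = [h.strip() for h in table[0]]
    rows = table[1:]
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    width = len(header)
    for k, row in enumerate(rows, start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {k}: expected {width} cells, found {len(row)}"
            )
    cidx = _resolve_class_column(header, class_column)

    labels = []
    for k, row in enumerate(rows, start=2):
        lab = row[cidx].strip()
        if lab in MISSING_TOKENS:
            raise ValidationError(f"{path}: line {k}: missing class value")
        labels.append(lab)

    pred_cols = [j for j in range(width) if j != cidx]
    schema: list[AttributeSchema] = []
    for pos, j in enumerate(pred_cols):
        cells = [row[j].strip() for row in rows]
        observed = [c for c in cells if c not in MISSING_TOKENS]
        if observed and all(_is_number(c) for c in observed):
            schema.append(AttributeSchema(header[j], NUMERIC, pos))
        else:
            cats = tuple(dict.fromkeys(observed)) or ("__empty__",)
            schema.append(AttributeSchema(header[j], NOMINAL, pos, cats))

    out_rows = []
    for row in rows:
        vals = []
        for attr, j in zip(schema, pred_cols):
            c = row[j].strip()
            if c in MISSING_TOKENS:
                vals.append(None)
            else:
                vals.append(float(c) if attr.is_numeric else c)
        out_rows.append(vals)
    return MixedDataset.from_rows(
        schema, out_rows, labels, class_name=header[cidx]
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _read_arff(path, class_column: str) -> MixedDataset:
    from scipy.io import arff as scipy_arff

    try:
        raw, meta = scipy_arff.loadarff(path)
    except Exception as exc:  # scipy raises ParseArffError with line info
        raise ParseError(f"{path}: {exc}") from exc
    names = list(meta.names())
    if not names:
        raise ParseError(f"{path}: no attribute declarations")
    cidx = _resolve_class_column(names, class_column)
    ctype, ccats = meta[names[cidx]]
    if ctype != "nominal":
        raise ConfigurationError(
            f"{path}: class attribute {names[cidx]!r} must be nominal"
        )
    schema: list[AttributeSchema] = []
    pred_names = [nm for k, nm in enumerate(names) if k != cidx]
    for pos, nm in enumerate(pred_names):
        kind, cats = meta[nm]
        if kind == "numeric":
            schema.append(AttributeSchema(nm, NUMERIC, pos))
        else:
            schema.append(AttributeSchema(nm, NOMINAL, pos, tuple(cats)))

    def _decode(v) -> str:
        return v.decode() if isinstance(v, bytes) else str(v)

    rows, labels = [], []
    for k, rec in enumerate(raw):
        lab = _decode(rec[names[cidx]])
        if lab == "?":
            raise ValidationError(f"{path}: data row {k}: missing class value")
        labels.append(lab)
        vals = []
        for attr, nm in zip(schema, pred_names):
            v = rec[nm]
            if attr.is_numeric:
                v = float(v)
                vals.append(None if math.isnan(v) else v)
            else:
                s = _decode(v)
                vals.append(None if s == "?" else s)
        rows.append(vals)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return MixedDataset.from_rows(
        schema, rows, labels, classes=list(ccats), class_name=names[cidx]
    )


def write_dataset(dataset: MixedDataset, path, format: str | None = None) -> None:
    """Write a dataset as CSV or ARFF (missing cells as ``"?"``).

    Numeric cells use ``repr`` so a write/read round trip preserves values
    to full precision.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(dataset, path)
    else:
        _write_arff(dataset, path)


def _format_cell(v) -> str:
    if v is None:
        return "?"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_csv(dataset: MixedDataset, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([a.name for a in dataset.schema] + [dataset.class_name])
        for inst in dataset:
            writer.writerow([_format_cell(v) for v in inst.values] + [inst.label])


def _arff_quote(token: str) -> str:
    if re.search(r"[\s,{}'\"%]", token) or token == "?":
        return "'" + token.replace("'", r"\'") + "'"
    return token


def _write_arff(dataset: MixedDataset, path) -> None:
    buf = io.StringIO()
    buf.write("@relation aisac\n\n")
    for attr in dataset.schema:
        if attr.is_numeric:
            buf.write(f"@attribute {_arff_quote(attr.name)} numeric\n")
        else:
            cats = ",".join(_arff_quote(c) for c in attr.categories)
            buf.write(f"@attribute {_arff_quote(attr.name)} {{{cats}}}\n")
    cls = ",".join(_arff_quote(c) for c in dataset.classes)
    buf.write(f"@attribute {_arff_quote(dataset.class_name)} {{{cls}}}\n")
    buf.write("\n@data\n")
    for inst in dataset:
        cells = [
            "?" if v is None else
            (repr(v) if isinstance(v, float) else _arff_quote(str(v)))
            for v in inst.values
        ]
        cells.append(_arff_quote(inst.label))
        buf.write(",".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Profiling


def truncate_ratio(numerator: int, denominator: int) -> str:
    """Render a count ratio truncated (not rounded) to 2 decimals.

    Published imbalance-ratio tables in this literature truncate: 187/175
    (= 1.0686) prints as ``"1.06"``.  Exact integer arithmetic avoids any
    floating-point edge case.
    """
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    hundredths = (100 * numerator) // denominator
    return f"{hundredths // 100}.{hundredths % 100:02d}"


@dataclass(frozen=True)
class DatasetProfile:
    """Summary characteristics of a dataset.

    ``imbalance_ratio`` is the majority/minority class-count ratio (global
    max over min for multiclass data); a dataset is conventionally called
    imbalanced when it exceeds 1.5.
    """

    n_attributes: int
    n_instances: int
    imbalance_ratio: float
    imbalance_ratio_display: str
    has_missing: bool
    class_counts: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "n_attributes": self.n_attributes,
            "n_instances": self.n_instances,
            "imbalance_ratio": self.imbalance_ratio,
            "imbalance_ratio_display": self.imbalance_ratio_display,
            "has_missing": self.has_missing,
            "class_counts": dict(self.class_counts),
        }


def profile(dataset: MixedDataset) -> DatasetProfile:
    """Compute counts, imbalance ratio and missingness flag for a dataset."""
    if dataset.n_instances == 0:
        raise ValidationError("cannot profile an empty dataset")
    counts = dataset.class_counts()
    present = {c: k for c, k in counts.items() if k > 0}
    maj = max(present.values())
    mino = min(present.values())
    return DatasetProfile(
        n_attributes=dataset.n_attributes,
        n_instances=dataset.n_instances,
        imbalance_ratio=maj / mino,
        imbalance_ratio_display=truncate_ratio(maj, mino),
        has_missing=dataset.has_missing(),
        class_counts=counts,
    )


# ---------------------------------------------------------------------------
# Stratified hold-out


def stratified_holdout(
    dataset: MixedDataset,
    fraction: float,
    seed: int | np.random.Generator,
) -> tuple[MixedDataset, MixedDataset]:
    """Split into (construction, validation) parts, stratified by class.

    Per class with ``n_c`` instances, ``round(fraction * n_c)`` (half up)
    go to the construction side, clamped so both sides keep at least one
    instance whenever ``n_c >= 2``.  A single-instance class goes entirely
    to construction.  Deterministic for a given seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError("holdout fraction must lie in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    con_idx: list[int] = []
    val_idx: list[int] = []
    for code in range(len(dataset.classes)):
        members = np.flatnonzero(dataset.y == code)
        n_c = len(members)
        if n_c == 0:
            continue
        order = rng.permutation(n_c)
        shuffled = members[order]
        if n_c == 1:
            con_idx.extend(shuffled.tolist())
            continue
        k = int(fraction * n_c + 0.5)  # round half up
        k = min(max(k, 1), n_c - 1)
        con_idx.extend(shuffled[:k].tolist())
        val_idx.extend(shuffled[k:].tolist())
    con_idx.sort()
    val_idx.sort()
    return dataset.subset(con_idx), dataset.subset(val_idx)
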