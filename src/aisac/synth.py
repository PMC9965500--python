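"""Synthetic mixed-type, incomplete, imbalanced classification data.

The generator emulates the character of the small clinical tabular
datasets this package targets: a handful to a few dozen predictive
attributes of mixed numeric/nominal type, tens to ~1400 instances, 2–3
classes with imbalance ratios roughly between 1 and 6, and optional
missing cells.  Class signal is controlled by a single ``class_separation``
knob with a uniform meaning across attribute kinds:

* numeric attributes are class-conditional Gaussians with unit
  within-class standard deviation and class means offset by
  ``class_separation`` standard deviations;
* nominal attributes concentrate probability mass on a class-preferred
  category, ``mass = 1/C + (1 - 1/C) * min(1, class_separation / 4)``,
  which is exactly uniform (no signal) at separation 0.

Missingness is MCAR: each predictive cell is independently blanked with
probability ``missing_rate``; class labels are never missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AttributeSchema, MixedDataset, NOMINAL, NUMERIC
from .exceptions import ConfigurationError

__all__ = ["GeneratorSpec", "generate", "inject_missing"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    Defaults describe a mid-sized imbalanced binary problem with mixed
    attributes, moderate class overlap and a realistic sprinkling of
    missing cells — the regime the targeted clinical datasets occupy.
    """

    n_instances: int = 300
    class_proportions: tuple[float, ...] = (0.7, 0.3)
    n_numeric: int = 4
    n_nominal: int = 3
    categories_per_nominal: int = 3
    class_separation: float = 2.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ConfigurationError("n_instances must be positive")
        props = tuple(float(p) for p in self.class_proportions)
        if len(props) < 2:
            raise ConfigurationError("need at least 2 classes")
        if any(p <= 0 for p in props):
            raise ConfigurationError("every class proportion must be > 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("class proportions must sum to 1")
        if self.n_numeric + self.n_nominal < 1:
            raise ConfigurationError("need at least one predictive attribute")
        if self.n_numeric < 0 or self.n_nominal < 0:
            raise ConfigurationError("attribute counts must be non-negative")
        if self.n_nominal > 0 and self.categories_per_nominal < 2:
            raise ConfigurationError("nominal attributes need >=2 categories")
        if self.class_separation < 0:
            raise ConfigurationError("class_separation must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "class_proportions", props)


def _schema(spec: GeneratorSpec) -> tuple[AttributeSchema, ...]:
    attrs = []
    cats = tuple(f"c{j}" for j in range(spec.categories_per_nominal))
    for j in range(spec.n_numeric):
        attrs.append(AttributeSchema(f"num{j}", NUMERIC, j))
    for j in range(spec.n_nominal):
        attrs.append(
            AttributeSchema(f"nom{j}", NOMINAL, spec.n_numeric + j, cats)
        )
    return tuple(attrs)


def generate(spec: GeneratorSpec) -> MixedDataset:
    """Draw one dataset according to ``spec``; deterministic given its seed."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.class_proportions)
    n = spec.n_instances
    if n < k:
        raise ConfigurationError("n_instances must be >= number of classes")
    # one guaranteed instance per class, remainder multinomial
    y = np.concatenate([
        np.arange(k),
        rng.choice(k, size=n - k, p=spec.class_proportions),
    ]).astype(np.int32)
    rng.shuffle(y)

    X_num = rng.normal(size=(n, spec.n_numeric))
    X_num += (y[:, None] * spec.class_separation)

    C = spec.categories_per_nominal
    X_nom = np.empty((n, spec.n_nominal), dtype=np.int32)
    if spec.n_nominal:
        mass = 1.0 / C + (1.0 - 1.0 / C) * min(1.0, spec.class_separation / 4.0)
        rest = (1.0 - mass) / (C - 1)
        u = rng.random((n, spec.n_nominal))
        for code in range(k):
            rows = y == code
            pref = code % C
            probs = np.full(C, rest)
            probs[pref] = mass
            cum = np.cumsum(probs)
            X_nom[rows] = np.searchsorted(cum, u[rows], side="right").astype(
                np.int32
            )
        np.clip(X_nom, 0, C - 1, out=X_nom)

    classes = tuple(f"class{c}" for c in range(k))
    ds = MixedDataset(_schema(spec), classes, X_num, X_nom, y)
    if spec.missing_rate > 0:
        ds = inject_missing(ds, spec.missing_rate, rng)
    return ds


def inject_missing(
    dataset: MixedDataset, rate: float, seed: int | np.random.Generator
) -> MixedDataset:
    """Blank each predictive cell independently with probability ``rate``.

    Labels are untouched and the input dataset is not modified.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("missing rate must lie in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n, m = dataset.n_instances, dataset.n_attributes
    mask = rng.random((n, m)) < rate
    X_num = dataset.X_num.copy()
    X_nom = dataset.X_nom.copy()
    for j, a in enumerate(dataset.numeric_attr_indices):
        X_num[mask[:, a], j] = np.nan
    for j, a in enumerate(dataset.nominal_attr_indices):
        X_nom[mask[:, a], j] = -1
    return MixedDataset(
        dataset.schema,
        dataset.classes,
        X_num,
        X_nom,
        dataset.y.copy(),
        class_name=dataset.class_name,
    )
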