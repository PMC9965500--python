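"""Shared fixtures: small hand-built datasets and evaluation helpers."""

from dataclasses import replace

import numpy as np
import pytest

from aisac import (
    AisacParams,
    AttributeSchema,
    GeneratorSpec,
    MixedDataset,
    balanced_accuracy,
    confusion_matrix,
    fit,
    generate,
    predict,
)


@pytest.fixture
def mixed_schema():
    return (
        AttributeSchema("age", "numeric", 0),
        AttributeSchema("mass", "nominal", 1, ("yes", "no")),
        AttributeSchema("density", "numeric", 2),
    )


@pytest.fixture
def small_dataset(mixed_schema):
    """6 rows, 2 classes, one missing cell."""
    rows = [
        (63.0, "yes", 2.0),
        (51.0, "no", 3.0),
        (44.0, "yes", None),
        (70.0, "no", 1.0),
        (58.0, "yes", 4.0),
        (39.0, "no", 2.0),
    ]
    labels = ["malignant", "benign", "malignant", "benign", "malignant", "benign"]
    return MixedDataset.from_rows(mixed_schema, rows, labels)


def heldout_ba(spec: GeneratorSpec, params: AisacParams, n_test: int = 200) -> float:
    """Fit on a generated dataset; balanced accuracy on a fresh draw."""
    train = generate(spec)
    memory = fit(train, params)
    test = generate(replace(spec, seed=spec.seed + 10_000, n_instances=n_test))
    preds = predict(memory, test)
    cm = confusion_matrix(
        [test.classes[c] for c in test.y], preds, memory.classes
    )
    return balanced_accuracy(cm).value


@pytest.fixture
def random_mixed_dataset():
    """Factory for random small mixed/incomplete datasets."""

    def make(rng: np.random.Generator, n_lo=20, n_hi=50) -> GeneratorSpec:
        k = int(rng.integers(2, 4))
        props = rng.dirichlet(np.ones(k) * 5.0)
        props = props / props.sum()
        props = tuple(float(p) for p in props)
        # renormalise exactly
        props = tuple(p / sum(props) for p in props)
        return GeneratorSpec(
            n_instances=int(rng.integers(n_lo, n_hi)),
            class_proportions=props,
            n_numeric=int(rng.integers(2, 5)),
            n_nominal=int(rng.integers(1, 4)),
            categories_per_nominal=int(rng.integers(2, 5)),
            class_separation=float(rng.uniform(0.0, 2.5)),
            missing_rate=float(rng.uniform(0.0, 0.15)),
            seed=int(rng.integers(2**31 - 1)),
        )

    return make
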