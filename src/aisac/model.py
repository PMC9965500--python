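"""AISAC-MMD: an artificial-immune-system prototype classifier that
operates natively on mixed and incomplete data.

The classifier builds a compact *immune memory* — a set of class-pure
prototypes ("antibodies") — from training data, and classifies an unknown
instance by the class of its HEOM-nearest prototype.  Training mimics an
adaptive immune response in four phases:

1. **Bagging** — each class is partitioned into class-pure clusters
   (bags) by drawing seed instances and assigning every remaining
   instance of the class to its HEOM-nearest seed.
2. **Merging** — each bag collapses into one prototype: attribute-wise
   mean (numeric) or mode (nominal) over the bag members' *observed*
   values; an attribute missing in every member stays missing, so
   prototypes never contain artificial values and the original training
   instances are never modified.
3. **Movement** — instances are tentatively reassigned between same-class
   bags; a move is kept only if it strictly improves the balanced
   accuracy of the nearest-prototype classifier on a held-out validation
   partition.
4. **Clonal selection** — each prototype spawns mutated clones (Gaussian
   perturbation of numerics scaled to the training range, random category
   flips for nominals); a prototype is replaced by its best clone only on
   strict validation improvement, which counteracts overfitting to the
   construction partition.

Phases 3 and 4 alternate for a bounded number of generations with early
stopping, under an elitist accept-only-if-better rule, so the validation
fitness trajectory is non-decreasing by construction.  Everything is
deterministic for a given (data, parameters, seed) triple.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .data import MixedDataset, AttributeSchema, stratified_holdout
from .exceptions import ConfigurationError, ValidationError
from .heom import RangeTable, get_dissimilarity
from .metrics import balanced_accuracy, confusion_matrix

__all__ = [
    "AisacParams",
    "Bag",
    "Prototype",
    "ImmuneMemory",
    "FitState",
    "build_bags",
    "merge_bag",
    "movement_pass",
    "clonal_pass",
    "fit",
    "classify",
    "predict",
]


@dataclass(frozen=True)
class AisacParams:
    """Training knobs of the immune classifier.

    Parameters
    ----------
    holdout_fraction
        Share of the training data used to construct prototypes; the
        remainder is the validation partition that drives fitness.
    bag_size
        Target number of instances per bag; a class with ``n_c``
        instances gets ``max(1, ceil(n_c / bag_size))`` bags.
    max_generations
        Upper bound on movement/clonal generations; 0 stops after the
        initial prototype set.
    n_clones
        Mutated copies generated per prototype in each clonal pass.
    mutation_rate
        Std-dev of numeric clone noise as a fraction of the training
        range; also the per-attribute probability of a nominal flip.
    patience
        Generations without validation improvement before early stop.
    seed
        Root seed; fully determines the fitted memory for fixed data.
    dissimilarity
        Named dissimilarity strategy ("heom" is the default and the one
        used throughout the experiments this package reproduces).
    """

    holdout_fraction: float = 0.7
    bag_size: int = 5
    max_generations: int = 10
    n_clones: int = 5
    mutation_rate: float = 0.1
    patience: int = 3
    seed: int = 0
    dissimilarity: str = "heom"

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ConfigurationError("holdout_fraction must lie in (0, 1)")
        if self.bag_size < 1:
            raise ConfigurationError("bag_size must be a positive integer")
        if self.max_generations < 0:
            raise ConfigurationError("max_generations must be >= 0")
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be a positive integer")
        if not (0.0 < self.mutation_rate <= 1.0):
            raise ConfigurationError("mutation_rate must lie in (0, 1]")
        if self.patience < 1:
            raise ConfigurationError("patience must be a positive integer")
        get_dissimilarity(self.dissimilarity)


@dataclass
class Bag:
    """A class-pure cluster of construction-set instances."""

    class_code: int
    members: list


@dataclass(frozen=True)
class Prototype:
    """A synthetic representative instance in the immune memory."""

    values: tuple
    label: str
    source: str


def build_bags(
    construction: MixedDataset,
    params: AisacParams,
    ranges: RangeTable | None = None,
    rng: np.random.Generator | int = 0,
) -> list[Bag]:
    """Phase 1: partition each class into bags around seeded leaders.

    Per class ``c`` with ``n_c`` instances, ``max(1, ceil(n_c /
    bag_size))`` seeds are drawn without replacement; every remaining
    instance of the class joins its HEOM-nearest seed (ties to the
    lowest seed index).
    """
    if construction.n_instances == 0:
        raise ValidationError("construction set is empty")
    if ranges is None:
        ranges = RangeTable.from_dataset(construction)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    metric = get_dissimilarity(params.dissimilarity)(construction.schema, ranges)
    bags: list[Bag] = []
    for code in range(len(construction.classes)):
        members = np.flatnonzero(construction.y == code)
        n_c = len(members)
        if n_c == 0:
            continue
        b_c = max(1, math.ceil(n_c / params.bag_size))
        seed_pos = np.sort(rng.choice(n_c, size=b_c, replace=False))
        seeds = members[seed_pos]
        class_bags = [Bag(code, [int(s)]) for s in seeds]
        rest = np.setdiff1d(members, seeds)
        if len(rest):
            D = metric.pairwise(
                construction.X_num[rest],
                construction.X_nom[rest],
                construction.X_num[seeds],
                construction.X_nom[seeds],
            )
            nearest = D.argmin(axis=1)  # first minimum = lowest seed index
            for i, s in zip(rest, nearest):
                class_bags[s].members.append(int(i))
        bags.extend(class_bags)
    return bags


def _merge_members(
    X_num: np.ndarray, X_nom: np.ndarray, members: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Attribute-wise mean/mode over a bag's observed values.

    Numeric: mean of non-missing member values.  Nominal: mode, with
    ties resolved to the category earliest in schema order (lowest
    code).  An attribute observed in no member stays missing.
    """
    if len(members) == 0:
        raise ValidationError("cannot merge an empty bag")
    idx = np.asarray(members, dtype=int)
    sub_num = X_num[idx]
    with np.errstate(all="ignore"):
        counts = (~np.isnan(sub_num)).sum(axis=0)
        sums = np.nansum(sub_num, axis=0)
        num = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    sub_nom = X_nom[idx]
    nom = np.full(X_nom.shape[1], -1, dtype=np.int32)
    for j in range(X_nom.shape[1]):
        col = sub_nom[:, j]
        col = col[col >= 0]
        if len(col):
            nom[j] = np.bincount(col).argmax()  # argmax -> lowest tied code
    return num, nom


def _decode_proto_values(
    schema: Sequence[AttributeSchema], num: np.ndarray, nom: np.ndarray
) -> tuple:
    out = []
    jn = jc = 0
    for attr in schema:
        if attr.is_numeric:
            v = num[jn]
            out.append(None if math.isnan(v) else float(v))
            jn += 1
        else:
            c = int(nom[jc])
            out.append(None if c < 0 else attr.categories[c])
            jc += 1
    return tuple(out)


def merge_bag(bag: Bag, construction: MixedDataset) -> Prototype:
    """Phase 2 for one bag: collapse its members into a prototype."""
    num, nom = _merge_members(construction.X_num, construction.X_nom, bag.members)
    return Prototype(
        values=_decode_proto_values(construction.schema, num, nom),
        label=construction.classes[bag.class_code],
        source=f"bag-{min(bag.members)}",
    )


def _class_priority(class_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-break ordering over classes: larger count first, then lower
    class index.  Returns (priority per class code, inverse map)."""
    k = len(class_counts)
    order = sorted(range(k), key=lambda c: (-int(class_counts[c]), c))
    priority = np.empty(k, dtype=np.int64)
    for rank, c in enumerate(order):
        priority[c] = rank
    inverse = np.asarray(order, dtype=np.int64)
    return priority, inverse


def _predict_codes(
    D: np.ndarray, proto_class: np.ndarray, priority: np.ndarray,
    priority_to_class: np.ndarray,
) -> np.ndarray:
    """Nearest-prototype class codes with the deterministic tie rule."""
    m = D.min(axis=1, keepdims=True)
    tie = D == m
    prio = np.where(tie, priority[proto_class][None, :], np.iinfo(np.int64).max)
    return priority_to_class[prio.min(axis=1)]


def _ba_codes(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> float:
    support = np.bincount(y_true, minlength=k)
    hits = np.bincount(y_true[y_true == y_pred], minlength=k)
    mask = support > 0
    return float(np.mean(hits[mask] / support[mask]))


class FitState:
    """Mutable training state shared by the movement and clonal passes.

    Holds the construction/validation partitions in columnar form, the
    current bags, the prototype arrays, the cached validation-to-
    prototype distance matrix and the current validation fitness.
    """

    def __init__(
        self,
        construction: MixedDataset,
        validation: MixedDataset,
        params: AisacParams,
        rng: np.random.Generator,
        class_counts: np.ndarray | None = None,
    ) -> None:
        self.con = construction
        self.val = validation
        self.params = params
        self.rng = rng
        self.ranges = RangeTable.from_dataset(construction)
        self.metric = get_dissimilarity(params.dissimilarity)(
            construction.schema, self.ranges
        )
        k = len(construction.classes)
        if class_counts is None:
            class_counts = np.bincount(construction.y, minlength=k)
        self.class_counts = np.asarray(class_counts)
        self.priority, self.priority_to_class = _class_priority(self.class_counts)

        self.bags = build_bags(construction, params, self.ranges, rng)
        self.bag_of = np.empty(construction.n_instances, dtype=np.int64)
        for bi, bag in enumerate(self.bags):
            for i in bag.members:
                self.bag_of[i] = bi
        P_num, P_nom = [], []
        for bag in self.bags:
            num, nom = _merge_members(
                construction.X_num, construction.X_nom, bag.members
            )
            P_num.append(num)
            P_nom.append(nom)
        self.P_num = np.vstack(P_num) if P_num else np.empty((0, 0))
        self.P_nom = (
            np.vstack(P_nom).astype(np.int32)
            if P_nom
            else np.empty((0, 0), dtype=np.int32)
        )
        self.p_class = np.asarray([b.class_code for b in self.bags])
        self.p_source = [f"bag-{min(b.members)}" for b in self.bags]
        self.D = self.metric.pairwise(
            validation.X_num, validation.X_nom, self.P_num, self.P_nom
        )
        self.fitness = self._fitness_from_D()

    # -- fitness -------------------------------------------------------

    def _fitness_from_D(self) -> float:
        if self.val.n_instances == 0:
            return 0.0
        pred = _predict_codes(
            self.D, self.p_class, self.priority, self.priority_to_class
        )
        return _ba_codes(self.val.y, pred, len(self.con.classes))

    def _fitness_with_cols(self, cols: list[int], new_cols: np.ndarray) -> float:
        if self.val.n_instances == 0:
            return 0.0
        saved = self.D[:, cols].copy()
        self.D[:, cols] = new_cols
        f = self._fitness_from_D()
        self.D[:, cols] = saved
        return f

    def _proto_column(self, num: np.ndarray, nom: np.ndarray) -> np.ndarray:
        return self.metric.pairwise(
            self.val.X_num, self.val.X_nom, num[None, :], nom[None, :]
        )[:, 0]

    def prototypes(self) -> list[Prototype]:
        return [
            Prototype(
                values=_decode_proto_values(
                    self.con.schema, self.P_num[b], self.P_nom[b]
                ),
                label=self.con.classes[self.p_class[b]],
                source=self.p_source[b],
            )
            for b in range(len(self.bags))
        ]


def movement_pass(state: FitState) -> bool:
    """Phase 3: one pass of instance moves between same-class bags.

    Visits every construction instance once in seeded random order; for
    each, evaluates reassignment to every other bag of its class
    (re-merging only the two affected prototypes) and applies the best
    such move if it strictly increases validation fitness.  Moves that
    would empty their source bag are not candidates.  Returns whether
    any move was accepted.
    """
    accepted = False
    order = state.rng.permutation(state.con.n_instances)
    for i in order:
        s = int(state.bag_of[i])
        if len(state.bags[s].members) <= 1:
            continue
        cls = int(state.con.y[i])
        dests = [
            t
            for t, bag in enumerate(state.bags)
            if bag.class_code == cls and t != s
        ]
        if not dests:
            continue
        src_members = [m for m in state.bags[s].members if m != i]
        s_num, s_nom = _merge_members(
            state.con.X_num, state.con.X_nom, src_members
        )
        col_s = state._proto_column(s_num, s_nom)
        best = None
        for t in dests:
            t_num, t_nom = _merge_members(
                state.con.X_num, state.con.X_nom, state.bags[t].members + [int(i)]
            )
            col_t = state._proto_column(t_num, t_nom)
            f = state._fitness_with_cols(
                [s, t], np.column_stack([col_s, col_t])
            )
            if best is None or f > best[0]:
                best = (f, t, t_num, t_nom, col_t)
        if best is not None and best[0] > state.fitness:
            f, t, t_num, t_nom, col_t = best
            state.bags[s].members = src_members
            state.bags[t].members.append(int(i))
            state.bag_of[i] = t
            state.P_num[s], state.P_nom[s] = s_num, s_nom
            state.P_num[t], state.P_nom[t] = t_num, t_nom
            state.p_source[s] = f"bag-{min(src_members)}"
            state.p_source[t] = f"bag-{min(state.bags[t].members)}"
            state.D[:, s] = col_s
            state.D[:, t] = col_t
            state.fitness = f
            accepted = True
    return accepted


def clonal_pass(state: FitState) -> bool:
    """Phase 4: clonal selection over the prototype set.

    Each prototype spawns ``n_clones`` mutated copies — numeric
    attributes get Gaussian noise with std ``mutation_rate * range``,
    clipped to the training [min, max]; nominal attributes are replaced
    by a uniformly drawn category with probability ``mutation_rate``;
    missing attributes stay missing.  A prototype is replaced by its
    best clone only on strict validation improvement.  Returns whether
    any replacement happened.
    """
    accepted = False
    params = state.params
    rng = state.rng
    m_num = state.P_num.shape[1]
    m_nom = state.P_nom.shape[1]
    nom_attrs = [a for a in state.con.schema if not a.is_numeric]
    for b in range(len(state.bags)):
        base_num = state.P_num[b]
        base_nom = state.P_nom[b]
        clones_num = np.tile(base_num, (params.n_clones, 1))
        if m_num:
            noise = rng.normal(
                0.0,
                params.mutation_rate * np.maximum(state.ranges.ranges, 0.0),
                size=(params.n_clones, m_num),
            )
            clones_num = np.clip(
                clones_num + noise, state.ranges.mins, state.ranges.maxs
            )  # NaN (missing) propagates through untouched
        clones_nom = np.tile(base_nom, (params.n_clones, 1))
        if m_nom:
            flip = rng.random((params.n_clones, m_nom)) < params.mutation_rate
            for j, attr in enumerate(nom_attrs):
                draw = rng.integers(
                    0, len(attr.categories), size=params.n_clones
                ).astype(np.int32)
                keep_missing = base_nom[j] < 0
                clones_nom[:, j] = np.where(
                    flip[:, j] & ~keep_missing, draw, base_nom[j]
                )
        best = None
        for c in range(params.n_clones):
            col = state._proto_column(clones_num[c], clones_nom[c])
            f = state._fitness_with_cols([b], col[:, None])
            if best is None or f > best[0]:
                best = (f, c, col)
        if best is not None and best[0] > state.fitness:
            f, c, col = best
            state.P_num[b] = clones_num[c]
            state.P_nom[b] = clones_nom[c]
            state.p_source[b] = "clone"
            state.D[:, b] = col
            state.fitness = f
            accepted = True
    return accepted


# ---------------------------------------------------------------------------
# Immune memory


class ImmuneMemory:
    """The fitted classifier: prototypes plus everything needed to
    classify and to re-evaluate the stored fitness."""

    def __init__(
        self,
        schema: Sequence[AttributeSchema],
        classes: Sequence[str],
        class_name: str,
        class_counts: dict,
        ranges: RangeTable,
        params: AisacParams,
        fitness: float,
        prototypes: Sequence[Prototype],
        validation: MixedDataset,
    ) -> None:
        self.schema = tuple(schema)
        self.classes = tuple(classes)
        self.class_name = class_name
        self.class_counts = dict(class_counts)
        self.ranges = ranges
        self.params = params
        self.fitness = float(fitness)
        self.prototypes = list(prototypes)
        self.validation = validation
        self._arrays: tuple | None = None

    # -- array view ----------------------------------------------------

    def _proto_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._arrays is None:
            rows = [p.values for p in self.prototypes]
            labels = [p.label for p in self.prototypes]
            ds = MixedDataset.from_rows(
                self.schema, rows, labels, classes=self.classes,
                class_name=self.class_name,
            )
            self._arrays = (ds.X_num, ds.X_nom, ds.y)
        return self._arrays

    def prototype_dataset(self) -> MixedDataset:
        """The prototype set viewed as a dataset (e.g. for 1-NN checks)."""
        return MixedDataset.from_rows(
            self.schema,
            [p.values for p in self.prototypes],
            [p.label for p in self.prototypes],
            classes=self.classes,
            class_name=self.class_name,
        )

    def reevaluate_fitness(self) -> float:
        """Balanced accuracy of the stored prototypes on the stored
        validation partition (should reproduce ``self.fitness``)."""
        if self.validation.n_instances == 0:
            return 0.0
        preds = predict(self, self.validation)
        cm = confusion_matrix(
            [self.classes[c] for c in self.validation.y], preds, self.classes
        )
        return balanced_accuracy(cm).value

    # -- persistence ----------------------------------------------------

    def to_json(self) -> str:
        d = {
            "format": "aisac-memory/1",
            "schema": [
                {
                    "name": a.name,
                    "kind": a.kind,
                    "index": a.index,
                    "categories": list(a.categories),
                }
                for a in self.schema
            ],
            "classes": list(self.classes),
            "class_name": self.class_name,
            "class_counts": {str(k): int(v) for k, v in self.class_counts.items()},
            "ranges": self.ranges.to_json_dict(),
            "params": asdict(self.params),
            "fitness": self.fitness,
            "prototypes": [
                {
                    "values": list(p.values),
                    "label": p.label,
                    "source": p.source,
                }
                for p in self.prototypes
            ],
            "validation": {
                "rows": [list(self.validation.row_values(i))
                         for i in range(self.validation.n_instances)],
                "labels": [self.validation.classes[c]
                           for c in self.validation.y],
            },
        }
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ImmuneMemory":
        d = json.loads(text)
        if d.get("format") != "aisac-memory/1":
            raise ValidationError("not an aisac memory file")
        schema = tuple(
            AttributeSchema(
                a["name"], a["kind"], a["index"], tuple(a["categories"])
            )
            for a in d["schema"]
        )
        classes = tuple(d["classes"])
        validation = MixedDataset.from_rows(
            schema,
            [tuple(r) for r in d["validation"]["rows"]],
            d["validation"]["labels"],
            classes=classes,
            class_name=d["class_name"],
        )
        return cls(
            schema=schema,
            classes=classes,
            class_name=d["class_name"],
            class_counts=d["class_counts"],
            ranges=RangeTable.from_json_dict(d["ranges"]),
            params=AisacParams(**d["params"]),
            fitness=d["fitness"],
            prototypes=[
                Prototype(tuple(p["values"]), p["label"], p["source"])
                for p in d["prototypes"]
            ],
            validation=validation,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ImmuneMemory":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def fit(training: MixedDataset, params: AisacParams | None = None) -> ImmuneMemory:
    """Train the immune classifier on a mixed/incomplete dataset.

    Splits the training data by stratified hold-out, runs the bagging and
    merging phases, then alternates movement and clonal passes for up to
    ``max_generations`` generations with early stopping after
    ``patience`` generations without validation improvement.  The
    original training instances are never modified.
    """
    if params is None:
        params = AisacParams()
    counts = np.bincount(training.y, minlength=len(training.classes))
    if np.count_nonzero(counts) < 2:
        raise ValidationError("training data must contain at least 2 classes")
    root = np.random.SeedSequence(params.seed)
    split_ss, evolve_ss = root.spawn(2)
    construction, validation = stratified_holdout(
        training, params.holdout_fraction, np.random.default_rng(split_ss)
    )
    state = FitState(
        construction,
        validation,
        params,
        np.random.default_rng(evolve_ss),
        class_counts=counts,
    )
    best = (state.fitness, state.P_num.copy(), state.P_nom.copy(),
            state.p_class.copy(), list(state.p_source))
    stale = 0
    for _ in range(params.max_generations):
        movement_pass(state)
        clonal_pass(state)
        if state.fitness > best[0]:
            best = (state.fitness, state.P_num.copy(), state.P_nom.copy(),
                    state.p_class.copy(), list(state.p_source))
            stale = 0
        else:
            stale += 1
            if stale >= params.patience:
                break
    fitness, P_num, P_nom, p_class, p_source = best
    prototypes = [
        Prototype(
            values=_decode_proto_values(training.schema, P_num[b], P_nom[b]),
            label=training.classes[p_class[b]],
            source=p_source[b],
        )
        for b in range(len(p_class))
    ]
    return ImmuneMemory(
        schema=training.schema,
        classes=training.classes,
        class_name=training.class_name,
        class_counts={c: int(k) for c, k in
                      zip(training.classes, counts)},
        ranges=state.ranges,
        params=params,
        fitness=fitness,
        prototypes=prototypes,
        validation=validation,
    )


def _encode_instance(memory: ImmuneMemory, values) -> tuple[np.ndarray, np.ndarray]:
    vals = values.values if hasattr(values, "values") and hasattr(values, "label") else values
    if len(vals) != len(memory.schema):
        raise ValidationError(
            f"instance has {len(vals)} values, schema expects "
            f"{len(memory.schema)}"
        )
    m_num = sum(a.is_numeric for a in memory.schema)
    m_nom = len(memory.schema) - m_num
    num = np.full(m_num, np.nan)
    nom = np.full(m_nom, -1, dtype=np.int32)
    jn = jc = 0
    for attr, v in zip(memory.schema, vals):
        if attr.is_numeric:
            if v is not None:
                num[jn] = float(v)
            jn += 1
        else:
            if v is not None:
                try:
                    nom[jc] = attr.categories.index(v)
                except ValueError:
                    raise ValidationError(
                        f"value {v!r} not among categories of {attr.name!r}"
                    ) from None
            jc += 1
    return num, nom


def _memory_priority(memory: ImmuneMemory) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(
        [memory.class_counts.get(c, 0) for c in memory.classes]
    )
    return _class_priority(counts)


def classify(memory: ImmuneMemory, x) -> str:
    """Class of the HEOM-nearest prototype; distance ties resolve to the
    class with the larger training count, then the lower class index.

    Total over any missingness pattern — an all-missing instance is
    equidistant from every prototype and receives the majority class.
    """
    num, nom = _encode_instance(memory, x)
    P_num, P_nom, p_y = memory._proto_arrays()
    metric = get_dissimilarity(memory.params.dissimilarity)(
        memory.schema, memory.ranges
    )
    D = metric.pairwise(num[None, :], nom[None, :], P_num, P_nom)
    priority, inverse = _memory_priority(memory)
    code = _predict_codes(D, p_y, priority, inverse)[0]
    return memory.classes[code]


def predict(memory: ImmuneMemory, dataset: MixedDataset) -> list[str]:
    """Vectorised :func:`classify` over every row of a dataset."""
    if tuple(a.kind for a in dataset.schema) != tuple(
        a.kind for a in memory.schema
    ):
        raise ValidationError("dataset schema does not match the memory schema")
    if dataset.schema == memory.schema:
        X_num, X_nom = dataset.X_num, dataset.X_nom
    else:
        # same kinds but different category codebooks: re-encode row-wise
        pairs = [
            _encode_instance(memory, dataset.row_values(i))
            for i in range(dataset.n_instances)
        ]
        X_num = np.vstack([p[0] for p in pairs])
        X_nom = np.vstack([p[1] for p in pairs]).astype(np.int32)
    P_num, P_nom, p_y = memory._proto_arrays()
    metric = get_dissimilarity(memory.params.dissimilarity)(
        memory.schema, memory.ranges
    )
    D = metric.pairwise(X_num, X_nom, P_num, P_nom)
    priority, inverse = _memory_priority(memory)
    codes = _predict_codes(D, p_y, priority, inverse)
    return [memory.classes[c] for c in codes]
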