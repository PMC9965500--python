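"""The four-phase immune classifier: bagging, merging, movement, clonal
selection, fitting, classification and persistence."""

import math
from dataclasses import replace

import numpy as np
import pytest

from aisac import (
    AisacParams,
    AttributeSchema,
    ConfigurationError,
    GeneratorSpec,
    ImmuneMemory,
    MixedDataset,
    ValidationError,
    build_bags,
    classify,
    clonal_pass,
    fit,
    generate,
    heom,
    merge_bag,
    movement_pass,
    nn_baseline,
    predict,
)
from aisac.heom import RangeTable
from aisac.model import FitState, _merge_members

NUM1 = (AttributeSchema("x", "numeric", 0),)


def _numeric_ds(values, labels, classes=None):
    return MixedDataset.from_rows(
        NUM1, [(float(v),) for v in values], labels, classes=classes
    )


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"holdout_fraction": 0.0},
            {"bag_size": 0},
            {"n_clones": 0},
            {"mutation_rate": 0.0},
            {"mutation_rate": 1.5},
            {"dissimilarity": "nope"},
        ],
    )
    def test_domain_validation(self, kwargs):
        with pytest.raises(ConfigurationError):
            AisacParams(**kwargs)


class TestBuildBags:
    def test_small_class_single_bag(self):
        ds = _numeric_ds([1, 2, 3], ["A", "A", "A"], classes=["A", "B"])
        bags = build_bags(ds, AisacParams(bag_size=5), rng=0)
        assert len(bags) == 1
        assert sorted(bags[0].members) == [0, 1, 2]

    def test_bag_size_one_gives_singletons(self):
        ds = _numeric_ds(range(6), ["A"] * 3 + ["B"] * 3)
        bags = build_bags(ds, AisacParams(bag_size=1), rng=0)
        assert len(bags) == 6
        assert all(len(b.members) == 1 for b in bags)

    def test_bag_count_and_class_purity(self):
        ds = _numeric_ds(range(12), ["A"] * 12, classes=["A", "B"])
        bags = build_bags(ds, AisacParams(bag_size=5), rng=3)
        assert len(bags) == math.ceil(12 / 5) == 3
        members = sorted(m for b in bags for m in b.members)
        assert members == list(range(12))

    def test_nearest_seed_assignment_replayed(self):
        """Non-seed instances join the HEOM-nearest seed (ties to the
        lowest seed index), replaying the seeded draw independently."""
        ds = _numeric_ds([0, 1, 2, 10, 11, 12, 20, 21, 22, 30, 31, 32],
                         ["A"] * 12, classes=["A", "B"])
        params = AisacParams(bag_size=4)
        rng_seed = 5
        bags = build_bags(ds, params, rng=rng_seed)
        # replay: identical generator stream, same draw
        rng = np.random.default_rng(rng_seed)
        seed_pos = np.sort(rng.choice(12, size=3, replace=False))
        ranges = RangeTable.from_dataset(ds)
        for i in range(12):
            if i in seed_pos:
                continue
            dists = [
                heom(ds.row_values(i), ds.row_values(int(s)), ds.schema, ranges)
                for s in seed_pos
            ]
            expected_seed = int(seed_pos[int(np.argmin(dists))])
            bag_of_i = next(b for b in bags if i in b.members)
            assert expected_seed in bag_of_i.members


class TestMergeBag:
    SCHEMA = (
        AttributeSchema("v", "numeric", 0),
        AttributeSchema("f", "nominal", 1, ("a", "b")),
    )

    def _ds(self, rows, labels):
        return MixedDataset.from_rows(self.SCHEMA, rows, labels)

    def test_singleton_bag_prototype_equals_instance(self):
        ds = self._ds([(2.0, None), (9.0, "b")], ["A", "B"])
        bags = build_bags(ds, AisacParams(bag_size=1), rng=0)
        bag_a = next(b for b in bags if ds.classes[b.class_code] == "A")
        proto = merge_bag(bag_a, ds)
        # missing cells are retained, not imputed
        assert proto.values == (2.0, None)
        assert proto.label == "A"

    def test_numeric_mean_over_observed(self):
        ds = self._ds([(2.0, "a"), (4.0, "a"), (None, "b")], ["A"] * 3)
        bags = build_bags(ds, AisacParams(bag_size=5), rng=0)
        assert merge_bag(bags[0], ds).values[0] == pytest.approx(3.0)

    def test_nominal_strict_mode(self):
        ds = self._ds([(1.0, "a"), (2.0, "a"), (3.0, "b")], ["A"] * 3)
        bags = build_bags(ds, AisacParams(bag_size=5), rng=0)
        assert merge_bag(bags[0], ds).values[1] == "a"

    def test_mode_tie_breaks_to_earliest_category(self):
        ds = self._ds([(1.0, "b"), (2.0, "a")], ["A"] * 2)
        bags = build_bags(ds, AisacParams(bag_size=5), rng=0)
        assert merge_bag(bags[0], ds).values[1] == "a"

    def test_attribute_missing_in_all_members_stays_missing(self):
        ds = self._ds([(None, "a"), (None, "b")], ["A"] * 2)
        bags = build_bags(ds, AisacParams(bag_size=5), rng=0)
        assert merge_bag(bags[0], ds).values[0] is None

    def test_empty_bag_rejected(self):
        with pytest.raises(ValidationError):
            _merge_members(np.zeros((2, 1)), np.zeros((2, 0), dtype=np.int32), [])


def _rebuild(state):
    """Recompute prototypes, distances and fitness from state.bags."""
    for bi, bag in enumerate(state.bags):
        num, nom = _merge_members(state.con.X_num, state.con.X_nom, bag.members)
        state.P_num[bi] = num
        state.P_nom[bi] = nom
        for m in bag.members:
            state.bag_of[m] = bi
    state.D = state.metric.pairwise(
        state.val.X_num, state.val.X_nom, state.P_num, state.P_nom
    )
    state.fitness = state._fitness_from_D()


def _two_cluster_state(seed=0):
    """Two tight clusters per class, plus validation points; bags are
    forced to the natural clusters."""
    con = _numeric_ds([0, 1, 20, 21, 6, 7, 26, 27],
                      ["A"] * 4 + ["B"] * 4)
    val = _numeric_ds([0.5, 7.5, 20.5, 26.5], ["A", "B", "A", "B"])
    state = FitState(con, val, AisacParams(bag_size=2, seed=seed),
                     np.random.default_rng(seed))
    cluster_members = [[0, 1], [2, 3], [4, 5], [6, 7]]
    for bag, members in zip(state.bags, cluster_members):
        bag.members = list(members)
    state.bags[0].class_code = state.bags[1].class_code = 0
    state.bags[2].class_code = state.bags[3].class_code = 1
    state.p_class = np.asarray([b.class_code for b in state.bags])
    _rebuild(state)
    return state


class TestMovementPass:
    def test_perfect_fitness_is_noop(self):
        state = _two_cluster_state()
        assert state.fitness == 1.0
        bags_before = [sorted(b.members) for b in state.bags]
        assert movement_pass(state) is False
        assert [sorted(b.members) for b in state.bags] == bags_before

    def test_single_bag_class_generates_no_moves(self):
        con = _numeric_ds([0, 1, 10, 11], ["A", "A", "B", "B"])
        val = _numeric_ds([0.5, 10.5], ["A", "B"])
        state = FitState(con, val, AisacParams(bag_size=5, seed=0),
                         np.random.default_rng(0))
        assert len(state.bags) == 2
        assert movement_pass(state) is False

    def test_swapped_instance_is_moved_back(self):
        """Deliberately misfile one instance; the pass must restore the
        exhaustively-best single-move configuration."""
        state = _two_cluster_state()
        # misfile construction instance 2 (value 20, class A) into the
        # near-origin bag of class A
        state.bags[0].members = [0, 1, 2]
        state.bags[1].members = [3]
        _rebuild(state)
        damaged = state.fitness
        assert damaged < 1.0
        # exhaustive check: the best single move restores fitness 1.0
        best = 0.0
        for i in range(state.con.n_instances):
            s = int(state.bag_of[i])
            if len(state.bags[s].members) <= 1:
                continue
            for t, bag in enumerate(state.bags):
                if t == s or bag.class_code != state.con.y[i]:
                    continue
                saved = [list(b.members) for b in state.bags]
                state.bags[s].members.remove(i)
                state.bags[t].members.append(i)
                _rebuild(state)
                best = max(best, state.fitness)
                for b, m in zip(state.bags, saved):
                    b.members = m
                _rebuild(state)
        assert best == 1.0
        assert movement_pass(state) is True
        assert state.fitness == 1.0 > damaged


class TestClonalPass:
    def test_fitness_never_decreases_and_clones_stay_in_range(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            spec = GeneratorSpec(
                n_instances=60,
                class_proportions=(0.6, 0.4),
                class_separation=float(rng.uniform(0.0, 2.0)),
                missing_rate=0.1,
                seed=int(rng.integers(2**31 - 1)),
            )
            ds = generate(spec)
            con, val = ds.subset(range(0, 40)), ds.subset(range(40, 60))
            state = FitState(con, val, AisacParams(seed=trial),
                             np.random.default_rng(trial))
            before = state.fitness
            clonal_pass(state)
            assert state.fitness >= before
            # numeric payloads clipped to the training range
            with np.errstate(invalid="ignore"):
                assert np.all(
                    np.isnan(state.P_num)
                    | (
                        (state.P_num >= state.ranges.mins - 1e-12)
                        & (state.P_num <= state.ranges.maxs + 1e-12)
                    )
                )


class TestFit:
    def test_same_seed_gives_byte_identical_memory(self):
        ds = generate(GeneratorSpec(seed=5, n_instances=120))
        m1 = fit(ds, AisacParams(seed=9, max_generations=3))
        m2 = fit(ds, AisacParams(seed=9, max_generations=3))
        assert m1.to_json() == m2.to_json()

    def test_training_data_never_modified(self):
        ds = generate(GeneratorSpec(seed=6, n_instances=100, missing_rate=0.1))
        num, nom, y = ds.X_num.copy(), ds.X_nom.copy(), ds.y.copy()
        fit(ds, AisacParams(seed=1, max_generations=2))
        assert np.array_equal(ds.X_num, num, equal_nan=True)
        assert np.array_equal(ds.X_nom, nom)
        assert np.array_equal(ds.y, y)

    def test_single_class_rejected(self):
        ds = _numeric_ds([1, 2, 3], ["A"] * 3)
        with pytest.raises(ValidationError):
            fit(ds, AisacParams())

    def test_every_training_class_represented(self):
        ds = generate(GeneratorSpec(
            seed=8, n_instances=90, class_proportions=(0.5, 0.3, 0.2)
        ))
        mem = fit(ds, AisacParams(seed=2, max_generations=1))
        assert {p.label for p in mem.prototypes} == set(ds.classes)

    def test_stored_fitness_matches_reevaluation(self):
        ds = generate(GeneratorSpec(seed=9, n_instances=120, missing_rate=0.08))
        mem = fit(ds, AisacParams(seed=3, max_generations=4))
        assert 0.0 <= mem.fitness <= 1.0
        assert mem.reevaluate_fitness() == pytest.approx(mem.fitness)

    def test_well_separated_data_high_heldout_accuracy(self):
        from conftest import heldout_ba

        spec = GeneratorSpec(
            n_instances=200, class_proportions=(0.5, 0.5),
            class_separation=4.0, missing_rate=0.0, seed=21,
        )
        assert heldout_ba(spec, AisacParams(seed=22)) > 0.95


class TestClassify:
    def _memory(self):
        ds = _numeric_ds([0, 0, 0, 10, 10], ["A"] * 3 + ["B"] * 2)
        return fit(ds, AisacParams(
            bag_size=5, max_generations=0, holdout_fraction=0.7, seed=0
        ))

    def test_instance_equal_to_prototype(self):
        mem = self._memory()
        p = mem.prototypes[0]
        assert classify(mem, p.values) == p.label

    def test_nearest_prototype_decision(self):
        mem = self._memory()
        assert classify(mem, (2.0,)) == "A"
        assert classify(mem, (9.0,)) == "B"

    def test_all_missing_gets_majority_class(self):
        mem = self._memory()
        # equidistant from every prototype -> tie -> larger class count
        assert classify(mem, (None,)) == "A"

    def test_schema_mismatch_rejected(self):
        mem = self._memory()
        with pytest.raises(ValidationError):
            classify(mem, (1.0, 2.0))


class TestDegenerateEquivalence:
    def test_singleton_bags_no_refinement_equals_1nn(self, random_mixed_dataset):
        """With bag_size=1 and no generations the memory is the
        construction set and predictions match the independent 1-NN/HEOM
        baseline (tie points checked by tie-class membership, since the
        two tie-break conventions differ)."""
        rng = np.random.default_rng(1717)
        params_base = AisacParams(
            bag_size=1, max_generations=0, holdout_fraction=0.9
        )
        checked = 0
        for _ in range(30):
            spec = random_mixed_dataset(rng)
            ds = generate(spec)
            mem = fit(ds, replace(params_base, seed=int(rng.integers(2**31 - 1))))
            proto_ds = mem.prototype_dataset()
            # singleton merging preserves every value, missing included
            test = generate(replace(spec, seed=spec.seed + 1, n_instances=15))
            preds = predict(mem, test)
            for i in range(test.n_instances):
                xs = test.row_values(i)
                dists = [
                    heom(xs, proto_ds.row_values(j), proto_ds.schema, mem.ranges)
                    for j in range(proto_ds.n_instances)
                ]
                dmin = min(dists)
                tie_classes = {
                    proto_ds.classes[proto_ds.y[j]]
                    for j, d in enumerate(dists)
                    if d <= dmin + 1e-9 * max(dmin, 1.0)
                }
                oracle = nn_baseline(proto_ds, xs, mem.ranges)
                if len(tie_classes) == 1:
                    assert preds[i] == oracle
                else:
                    assert preds[i] in tie_classes and oracle in tie_classes
                checked += 1
        assert checked == 30 * 15


class TestPersistence:
    def test_json_round_trip_is_bit_exact(self, tmp_path):
        ds = generate(GeneratorSpec(seed=13, n_instances=80, missing_rate=0.1))
        mem = fit(ds, AisacParams(seed=4, max_generations=2))
        path = tmp_path / "m.json"
        mem.save(path)
        back = ImmuneMemory.load(path)
        assert back.to_json() == mem.to_json()
        assert predict(back, ds) == predict(mem, ds)

    def test_params_and_missing_markers_survive(self, tmp_path):
        ds = generate(GeneratorSpec(seed=14, n_instances=60, missing_rate=0.3))
        params = AisacParams(seed=5, bag_size=3, mutation_rate=0.2,
                             max_generations=1)
        mem = fit(ds, params)
        path = tmp_path / "m.json"
        mem.save(path)
        back = ImmuneMemory.load(path)
        assert back.params == params
        missing_before = [
            [v is None for v in p.values] for p in mem.prototypes
        ]
        missing_after = [
            [v is None for v in p.values] for p in back.prototypes
        ]
        assert missing_before == missing_after
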