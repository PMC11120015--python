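"""Entropy/gain closed forms, split search, tree building and prediction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npulud import (
    NEGATIVE,
    POSITIVE,
    ClassCounts,
    FormatError,
    NeighborConfig,
    ParameterError,
    best_split,
    build_tree,
    deserialize,
    entropy,
    expected_entropy,
    gain_ratio,
    information_gain,
    predict,
    predict_dataset,
    relabel_unlabeled,
    serialize,
    split_information,
    toy_fixture,
)
from npulud.dataset_core import FeatureSpec, Instance, PUDataset
from npulud.decision_tree import GAIN_TOL


def counts(*pairs):
    return ClassCounts(counts=tuple(pairs))


def _partition_toy_at(ds, j, threshold):
    left = [i for i in ds.instances if i.values[j] <= threshold]
    right = [i for i in ds.instances if i.values[j] > threshold]
    return [
        ClassCounts.from_labels(i.observed_label for i in left),
        ClassCounts.from_labels(i.observed_label for i in right),
    ]


class TestEntropy:
    def test_toy_class_totals(self):
        assert entropy(counts((POSITIVE, 11), (NEGATIVE, 9))) == pytest.approx(
            0.99277, abs=1e-5
        )

    def test_pure_node_is_zero(self):
        assert entropy(counts((POSITIVE, 10))) == 0.0

    def test_balanced_binary_is_one_bit(self):
        assert entropy(counts((POSITIVE, 5), (NEGATIVE, 5))) == 1.0

    def test_empty_node_rejected(self):
        with pytest.raises(ParameterError):
            entropy(counts())

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=5).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_log2_m_and_label_permutation_invariant(self, raw):
        cc = counts(*((f"c{i}", c) for i, c in enumerate(raw)))
        h = entropy(cc)
        m = len(raw)
        assert -1e-12 <= h <= math.log2(m) + 1e-12 if m > 1 else h == 0.0
        flipped = counts(*((f"c{i}", c) for i, c in enumerate(reversed(raw))))
        assert entropy(flipped) == pytest.approx(h, abs=1e-12)


class TestExpectedEntropyAndGain:
    def test_toy_weight_split_expected_entropy(self, toy_supervised):
        parent = counts((POSITIVE, 11), (NEGATIVE, 9))
        part = _partition_toy_at(toy_supervised, 0, 4.0)
        assert expected_entropy(parent, part) == pytest.approx(0.37622, abs=1e-5)

    def test_toy_weight_split_gain(self, toy_supervised):
        parent = counts((POSITIVE, 11), (NEGATIVE, 9))
        part = _partition_toy_at(toy_supervised, 0, 4.0)
        assert information_gain(parent, part) == pytest.approx(0.61655, abs=1e-5)

    def test_toy_weight_split_gain_ratio(self, toy_supervised):
        parent = counts((POSITIVE, 11), (NEGATIVE, 9))
        part = _partition_toy_at(toy_supervised, 0, 4.0)
        assert gain_ratio(parent, part) == pytest.approx(0.62104, abs=1e-5)

    def test_pure_parent_partition_has_zero_expected_entropy(self):
        parent = counts((POSITIVE, 6))
        part = [counts((POSITIVE, 2)), counts((POSITIVE, 4))]
        assert expected_entropy(parent, part) == 0.0
        assert gain_ratio(parent, part) == 0.0

    def test_single_branch_partition_is_identity_and_skip_signal(self):
        parent = counts((POSITIVE, 3), (NEGATIVE, 3))
        part = [parent]
        assert expected_entropy(parent, part) == pytest.approx(entropy(parent))
        assert information_gain(parent, part) == pytest.approx(0.0, abs=1e-12)
        assert gain_ratio(parent, part) is None  # zero split information

    def test_perfect_split_gain_equals_parent_entropy(self):
        parent = counts((POSITIVE, 7), (NEGATIVE, 3))
        part = [counts((POSITIVE, 7)), counts((NEGATIVE, 3))]
        assert information_gain(parent, part) == pytest.approx(entropy(parent))

    def test_equal_halves_split_information_is_one_bit(self):
        parent = counts((POSITIVE, 4), (NEGATIVE, 4))
        part = [counts((POSITIVE, 4)), counts((NEGATIVE, 4))]
        assert split_information(parent, part) == pytest.approx(1.0)
        assert gain_ratio(parent, part) == pytest.approx(information_gain(parent, part))

    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=2, max_size=5
        ).filter(lambda parts: sum(a + b for a, b in parts) > 0)
    )
    @settings(max_examples=200, derandomize=True)
    def test_gain_is_never_negative(self, parts):
        children = [counts((POSITIVE, a), (NEGATIVE, b)) for a, b in parts]
        tp = sum(a for a, _ in parts)
        tn = sum(b for _, b in parts)
        parent = counts((POSITIVE, tp), (NEGATIVE, tn))
        assert information_gain(parent, children) >= -1e-12


def brute_force_best_split(instances, specs, criterion):
    """Independent oracle: enumerate every candidate and score directly."""
    best = None
    for j, spec in enumerate(specs):
        if spec.kind != "numeric":
            continue
        vals = sorted({i.values[j] for i in instances})
        for lo, hi in zip(vals, vals[1:]):
            t = (lo + hi) / 2
            left = [i.observed_label for i in instances if i.values[j] <= t]
            right = [i.observed_label for i in instances if i.values[j] > t]
            if not left or not right:
                continue
            parent = ClassCounts.from_labels(i.observed_label for i in instances)
            part = [ClassCounts.from_labels(left), ClassCounts.from_labels(right)]
            g = information_gain(parent, part)
            if g <= GAIN_TOL:
                continue
            score = g if criterion == "gain" else gain_ratio(parent, part)
            if score is None:
                continue
            key = (-score, j, t)
            if best is None or key < best[0]:
                best = (key, j, t)
    return None if best is None else (best[1], best[2])


class TestBestSplit:
    def test_toy_root_is_weight_threshold_between_4_and_6(self, toy_supervised):
        cand = best_split(toy_supervised.instances, toy_supervised.specs)
        assert cand.feature_index == 0
        assert 4.0 < cand.threshold < 6.0

    def test_identical_feature_vectors_give_no_split(self):
        specs = [FeatureSpec("x", "numeric", observed_range=(1.0, 1.0))]
        rows = [
            Instance(1, (1.0,), POSITIVE, POSITIVE),
            Instance(2, (1.0,), NEGATIVE, NEGATIVE),
        ]
        assert best_split(rows, specs) is None

    def test_separating_threshold_attains_parent_entropy(self):
        specs = [FeatureSpec("x", "numeric", observed_range=(0.0, 1.0))]
        rows = [
            Instance(1, (0.0,), POSITIVE, POSITIVE),
            Instance(2, (0.0,), POSITIVE, POSITIVE),
            Instance(3, (1.0,), NEGATIVE, NEGATIVE),
            Instance(4, (1.0,), NEGATIVE, NEGATIVE),
        ]
        cand = best_split(rows, specs)
        assert cand.threshold == 0.5
        assert cand.gain == pytest.approx(1.0)

    def test_categorical_multiway_split(self):
        specs = [FeatureSpec("c", "categorical", categories=("a", "b", "c"))]
        rows = [
            Instance(1, ("a",), POSITIVE, POSITIVE),
            Instance(2, ("a",), POSITIVE, POSITIVE),
            Instance(3, ("b",), NEGATIVE, NEGATIVE),
            Instance(4, ("c",), NEGATIVE, NEGATIVE),
        ]
        cand = best_split(rows, specs)
        assert cand.kind == "categorical_multiway"
        assert cand.branch_values == ("a", "b", "c")
        assert cand.gain == pytest.approx(1.0)

    @pytest.mark.parametrize("criterion", ["gain", "gain_ratio"])
    def test_agrees_with_brute_force_oracle(self, criterion, gaussian_separated):
        ds = gaussian_separated.unmask()
        cand = best_split(ds.instances, ds.specs, criterion=criterion)
        oracle = brute_force_best_split(ds.instances, ds.specs, criterion)
        assert (cand.feature_index, cand.threshold) == oracle

    def test_toy_both_criteria_agree_with_oracle(self, toy_supervised):
        for criterion in ("gain", "gain_ratio"):
            cand = best_split(toy_supervised.instances, toy_supervised.specs, criterion=criterion)
            oracle = brute_force_best_split(toy_supervised.instances, toy_supervised.specs, criterion)
            assert (cand.feature_index, cand.threshold) == oracle


class TestBuildTreeAndPredict:
    def test_toy_tree_classifies_all_training_instances(self, toy_pu, toy_supervised):
        relabeled, _ = relabel_unlabeled(toy_pu, NeighborConfig(k=3))
        model = build_tree(relabeled)
        preds = predict_dataset(model, toy_supervised)
        assert all(
            preds[i.id] == i.true_label for i in toy_supervised.instances
        )
        # structure: weight threshold at the root, count threshold beneath
        assert model.root.feature_index == 0
        assert 4.0 < model.root.threshold < 6.0
        inner = [c for c in model.root.children if not c.is_leaf]
        assert len(inner) == 1 and inner[0].feature_index == 1

    def test_narrative_predictions(self, toy_pu):
        relabeled, _ = relabel_unlabeled(toy_pu)
        model = build_tree(relabeled)
        light = Instance(100, (3.0, 4.0), POSITIVE, POSITIVE)
        heavy = Instance(101, (10.0, 8.0), NEGATIVE, NEGATIVE)
        assert predict(model, light) == POSITIVE
        assert predict(model, heavy) == NEGATIVE

    def test_single_class_training_set_is_one_leaf(self):
        specs = [FeatureSpec("x", "numeric", observed_range=(0.0, 5.0))]
        rows = [Instance(i, (float(i),), POSITIVE, POSITIVE) for i in range(5)]
        model = build_tree(PUDataset(specs=specs, instances=rows))
        assert model.root.is_leaf
        assert model.root.prediction == POSITIVE

    def test_contradictory_duplicates_fall_back_to_tie_rule(self):
        specs = [FeatureSpec("x", "numeric", observed_range=(1.0, 1.0))]
        rows = [
            Instance(1, (1.0,), POSITIVE, POSITIVE),
            Instance(2, (1.0,), NEGATIVE, NEGATIVE),
        ]
        model = build_tree(PUDataset(specs=specs, instances=rows))
        assert model.root.is_leaf
        assert model.root.prediction == POSITIVE  # tie -> positive

    def test_unlabeled_instance_is_a_precondition_error(self, toy_pu):
        with pytest.raises(ParameterError):
            build_tree(toy_pu)

    def test_duplicate_free_data_reaches_full_training_accuracy(self, gaussian_separated):
        ds = gaussian_separated.unmask()
        model = build_tree(ds, min_leaf=1)
        preds = predict_dataset(model, ds)
        assert all(preds[i.id] == i.observed_label for i in ds.instances)

    def test_missing_value_routes_to_largest_child(self, toy_pu):
        relabeled, _ = relabel_unlabeled(toy_pu)
        model = build_tree(relabeled)
        ghost = Instance(200, (None, None), POSITIVE, POSITIVE)
        assert predict(model, ghost) in (POSITIVE, NEGATIVE)  # total function

    def test_leaf_counts_sum_to_training_size(self, toy_pu):
        relabeled, _ = relabel_unlabeled(toy_pu)
        model = build_tree(relabeled)

        def leaf_total(node):
            if node.is_leaf:
                return node.counts.total
            return sum(leaf_total(c) for c in node.children)

        assert leaf_total(model.root) == 20


class TestSerialization:
    def test_round_trip_preserves_predictions_and_structure(self, toy_pu, toy_supervised):
        relabeled, _ = relabel_unlabeled(toy_pu)
        model = build_tree(relabeled)
        back = deserialize(serialize(model))
        assert back.node_count() == model.node_count()
        for inst in toy_supervised.instances:
            assert predict(back, inst) == predict(model, inst)

    def test_round_trip_is_textually_stable(self, toy_pu):
        relabeled, _ = relabel_unlabeled(toy_pu)
        doc = serialize(build_tree(relabeled))
        assert serialize(deserialize(doc)) == doc

    def test_truncated_document_is_a_format_error(self, toy_pu):
        relabeled, _ = relabel_unlabeled(toy_pu)
        doc = serialize(build_tree(relabeled))
        with pytest.raises(FormatError):
            deserialize(doc[: len(doc) // 2])

    def test_wrong_format_marker_rejected(self):
        with pytest.raises(FormatError):
            deserialize('{"format": "something-else"}')
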