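"""Evaluation metrics, protocols and the significance test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, special, stats

from ecknn.classifier import brknn, zero_rule_factory
from ecknn.dataset import make_folds
from ecknn.ec import expand_label_set, parse_ec
from ecknn.metrics import (
    confusion_counts,
    cross_evaluate,
    digit_histogram,
    leave_group_out,
    micro_macro_example_metrics,
    per_main_class_accuracy,
    significance,
    subset_accuracy,
)

E = lambda *ecs: frozenset(parse_ec(e) for e in ecs)
CHAIN = E("1.-.-.-", "1.2.-.-", "1.2.3.-", "1.2.3.4")
PARTIAL = E("1.-.-.-", "1.2.-.-", "1.2.3.-")


class TestSubsetAccuracy:
    def test_missing_one_label_counts_as_completely_incorrect(self):
        assert subset_accuracy([CHAIN], [PARTIAL]) == 0.0

    def test_exact_match_scores_one(self):
        assert subset_accuracy([CHAIN], [CHAIN]) == 1.0

    def test_empty_empty_is_a_match(self):
        assert subset_accuracy([frozenset()], [frozenset()]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            subset_accuracy([CHAIN], [])


class TestAveragedMetrics:
    def test_perfect_prediction(self):
        truth = [CHAIN, frozenset(), E("2.2.2.2")]
        m = micro_macro_example_metrics(truth, truth)
        assert all(v == 1.0 for v in m.values())

    def test_hand_computed_micro_macro(self):
        # label A: TP=1, FP=1; label B: TP=0, FN=1
        a, b = parse_ec("1.-.-.-"), parse_ec("2.-.-.-")
        truth = [frozenset({a}), frozenset(), frozenset({b})]
        pred = [frozenset({a}), frozenset({a}), frozenset()]
        m = micro_macro_example_metrics(truth, pred)
        assert m["micro_precision"] == 0.5
        assert m["micro_recall"] == 0.5
        assert m["macro_precision"] == 0.25
        assert m["macro_recall"] == 0.5

    def test_example_based_overlap(self):
        x, y = parse_ec("1.-.-.-"), parse_ec("2.-.-.-")
        m = micro_macro_example_metrics(
            [frozenset({x})], [frozenset({x, y})]
        )
        assert m["example_precision"] == 0.5
        assert m["example_recall"] == 1.0
        assert m["example_accuracy"] == 0.5

    def test_empty_empty_instance_contributes_one(self):
        m = micro_macro_example_metrics([frozenset()], [frozenset()])
        assert m["example_precision"] == 1.0
        assert m["example_accuracy"] == 1.0

    def test_micro_matches_per_label_loop_oracle(self, small_dataset):
        from ecknn.classifier import fit

        ds, _ = small_dataset
        train = ds.subset(range(0, len(ds), 2))
        test = ds.subset(range(1, len(ds), 2))
        preds = fit(train, 1).predict([i.signatures for i in test.instances])
        truth = [i.labels for i in test.instances]
        m = micro_macro_example_metrics(truth, preds.label_sets(), ds.label_space)
        counts = confusion_counts(truth, preds.label_sets(), ds.label_space)
        tp = sum(c.tp for c in counts.values())
        fp = sum(c.fp for c in counts.values())
        fn = sum(c.fn for c in counts.values())
        assert m["micro_precision"] == pytest.approx(tp / (tp + fp))
        assert m["micro_recall"] == pytest.approx(tp / (tp + fn))

    def test_confusion_rows_sum_to_instance_count(self, small_dataset):
        ds, _ = small_dataset
        truth = [i.labels for i in ds.instances]
        counts = confusion_counts(truth, truth, ds.label_space)
        for c in counts.values():
            assert c.tp + c.fp + c.fn + c.tn == len(ds)

    @given(
        st.lists(
            st.tuples(
                st.frozensets(st.sampled_from(["1.1.1.1", "2.2.2.2", "3.3.-.-"]), max_size=3),
                st.frozensets(st.sampled_from(["1.1.1.1", "2.2.2.2", "3.3.-.-"]), max_size=3),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_subset_accuracy_is_strictest(self, pairs):
        truth = [expand_label_set({parse_ec(e) for e in t}) for t, _ in pairs]
        pred = [expand_label_set({parse_ec(e) for e in p}) for _, p in pairs]
        m = micro_macro_example_metrics(truth, pred)
        assert subset_accuracy(truth, pred) <= m["example_accuracy"] + 1e-12 <= 1 + 1e-12


class TestDigitHistogram:
    def test_full_chain_counts_once_at_depth_four(self):
        assert digit_histogram([CHAIN]) == {1: 0, 2: 0, 3: 0, 4: 1}

    def test_empty_set_counts_nothing(self):
        assert digit_histogram([frozenset()]) == {1: 0, 2: 0, 3: 0, 4: 0}

    def test_mixed_depths(self):
        hist = digit_histogram([E("1.2.-.-"), E("2.-.-.-")])
        assert hist == {1: 1, 2: 1, 3: 0, 4: 0}

    def test_two_chains_in_one_set(self):
        hist = digit_histogram([CHAIN | E("2.-.-.-", "2.3.-.-")])
        assert hist == {1: 0, 2: 1, 3: 0, 4: 1}


class TestPerMainClass:
    def test_all_correct(self):
        truth = [CHAIN, E("2.2.2.2"), frozenset()]
        acc = per_main_class_accuracy(truth, truth)
        assert acc == {"EC1": 1.0, "EC2": 1.0, "no-EC": 1.0}

    def test_non_enzymes_all_predicted_enzyme(self):
        truth = [frozenset(), frozenset()]
        pred = [E("1.1.1.1"), E("2.2.2.2")]
        assert per_main_class_accuracy(truth, pred)["no-EC"] == 0.0

    def test_matches_filter_then_score_oracle(self, small_dataset):
        from ecknn.classifier import fit

        ds, _ = small_dataset
        train = ds.subset(range(0, len(ds), 2))
        test = ds.subset(range(1, len(ds), 2))
        preds = fit(train, 1).predict([i.signatures for i in test.instances])
        truth = [i.labels for i in test.instances]
        acc = per_main_class_accuracy(truth, preds.label_sets())
        for key, value in acc.items():
            if key == "no-EC":
                idx = [i for i, t in enumerate(truth) if not t]
            else:
                mc = int(key[2:])
                idx = [
                    i for i, t in enumerate(truth)
                    if any(l.main_class == mc for l in t)
                ]
            expected = subset_accuracy(
                [truth[i] for i in idx], [preds.label_sets()[i] for i in idx]
            )
            assert value == pytest.approx(expected)


class TestCrossEvaluate:
    def test_noise_free_recovery(self, default_dataset):
        """Clean class-combination data is almost perfectly recoverable."""
        ds, _ = default_dataset
        folds = make_folds(ds, 10, rounds=1, seed=1)
        report = cross_evaluate(ds, brknn(1), folds)
        assert report["subset_accuracy"] >= 0.95

    def test_zero_rule_matches_majority_fraction(self, default_dataset):
        ds, _ = default_dataset
        folds = make_folds(ds, 10, rounds=1, seed=1)
        report = cross_evaluate(ds, zero_rule_factory(), folds)
        pooled = (
            report.folds["subset_accuracy"] * report.folds["n_test"]
        ).sum() / report.folds["n_test"].sum()
        n_non = sum(1 for i in ds.instances if not i.labels)
        assert pooled == pytest.approx(n_non / len(ds))
        assert report["subset_accuracy"] == pytest.approx(0.45, abs=0.01)

    def test_deterministic_given_seed(self, small_dataset):
        ds, _ = small_dataset
        folds = make_folds(ds, 5, rounds=2, seed=3)
        r1 = cross_evaluate(ds, brknn(1), folds)
        r2 = cross_evaluate(ds, brknn(1), folds)
        assert r1.folds.equals(r2.folds)

    def test_report_summary_and_csv(self, small_dataset, tmp_path):
        ds, _ = small_dataset
        folds = make_folds(ds, 5, rounds=1, seed=3)
        report = cross_evaluate(ds, brknn(1), folds)
        summary = report.summary()
        assert "subset_accuracy" in summary.index
        assert (summary["mean"] <= 1).all() and (summary["mean"] >= 0).all()
        assert report.sd is not None
        out = tmp_path / "report.csv"
        report.to_csv(out)
        import pandas as pd

        back = pd.read_csv(out)
        assert {"round", "fold", "metric", "value"} <= set(back.columns)
        assert (back["fold"] == "mean").sum() == len(report.metric_names)


class TestLeaveGroupOut:
    def test_duplicated_group_scores_perfectly(self, small_dataset):
        """Held-out vectors duplicated in training are matched at distance 0."""
        from ecknn.dataset import AnnotatedDataset, Instance

        ds, _ = small_dataset
        base = ds.instances[:40]
        copies = tuple(
            Instance(f"copy_{i.id}", i.signatures, i.labels, {"species": "heldout"})
            for i in base
        )
        merged = AnnotatedDataset(
            ds.signature_vocabulary, ds.label_space, ds.instances + copies
        )
        report = leave_group_out(merged, "species", "heldout", brknn(1))
        assert report["subset_accuracy"] == 1.0

    def test_unseen_labels_cannot_be_predicted(self, small_dataset):
        ds, _ = small_dataset
        # mark the carriers of one label as a group of their own
        from ecknn.dataset import AnnotatedDataset, Instance

        target = next(
            i.labels for i in ds.instances if len(i.labels) >= 4
        )
        instances = tuple(
            Instance(
                i.id, i.signatures, i.labels,
                {"species": "exotic" if i.labels == target else "common"},
            )
            for i in ds.instances
        )
        merged = AnnotatedDataset(ds.signature_vocabulary, ds.label_space, instances)
        report = leave_group_out(merged, "species", "exotic", brknn(1))
        assert report["subset_accuracy"] == 0.0
        assert report["micro_recall"] < 1.0

    def test_inverse_mode_scores_complement(self, small_dataset):
        ds, _ = small_dataset
        report = leave_group_out(ds, "species", "species_01", brknn(1), inverse=True)
        n_in_group = sum(
            1 for i in ds.instances if i.groups.get("species") == "species_01"
        )
        assert int(report.folds["n_test"].iloc[0]) == len(ds) - n_in_group
        assert report.per_main_class is not None
        assert report.digit_histogram_predicted is not None


def t_density(x, r):
    """Student-t probability density, written from the Gamma-function form."""
    return (
        special.gamma((r + 1) / 2)
        / (math.sqrt(r * math.pi) * special.gamma(r / 2))
        * (1 + x * x / r) ** (-(r + 1) / 2)
    )


class TestSignificance:
    def test_identical_samples(self):
        r = significance([0.5, 0.6, 0.7], [0.7, 0.6, 0.5])
        assert r.t == 0.0 and r.p_value == 1.0 and not r.significant

    def test_separated_samples(self):
        r = significance([1, 2, 3], [101, 102, 103])
        assert abs(r.t) > 100 and r.p_value < 1e-4 and r.significant

    def test_reference_sd_formula(self):
        # mean 0.9, other mean 0.88, n=10 -> t = 0.02 / (sd / sqrt(10))
        a = np.array([0.89, 0.91] * 5)
        sd = a.std(ddof=1)
        b = np.full(10, 0.88)
        r = significance(a, b)
        expected_t = (0.9 - 0.88) / (sd / math.sqrt(10))
        assert r.t == pytest.approx(expected_t)

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.5, 6.3245])
    @pytest.mark.parametrize("df", [3, 9, 19])
    def test_p_matches_density_quadrature(self, t, df):
        tail, _ = integrate.quad(t_density, t, np.inf, args=(df,))
        expected = 2 * tail
        p = 2 * stats.t.sf(t, df)  # the implementation's formula
        assert p == pytest.approx(expected, abs=1e-6)
        # and through the public API with samples engineered to give t
        n = df + 1
        a = np.array([1.0, -1.0] * (n // 2) + ([0.0] if n % 2 else []))
        a = a - a.mean()
        sd = a.std(ddof=1)
        shift = t * sd / math.sqrt(n)
        r = significance(a + shift, np.zeros(n))
        assert r.t == pytest.approx(t, rel=1e-9)
        assert r.p_value == pytest.approx(expected, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            significance([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            significance([1.0, 1.0, 1.0], [0.5, 0.6, 0.7])

    @given(st.floats(min_value=0.01, max_value=50), st.integers(min_value=2, max_value=40))
    def test_p_value_properties(self, t, df):
        p_pos = 2 * stats.t.sf(abs(t), df)
        p_neg = 2 * stats.t.sf(abs(-t), df)
        assert p_pos == p_neg
        assert 0 < p_pos <= 1
        assert 2 * stats.t.sf(abs(t) + 1.0, df) < p_pos  # decreasing in |t|
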