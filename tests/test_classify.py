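"""Confusion metrics, ROC AUC, classifier training, agreement and group
comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import tonguefusion as tf
from oracles import auc_pairs, confusion_bruteforce


class TestConfusionMetrics:
    def test_hand_example(self):
        m = tf.confusion_metrics(tf.ConfusionCounts(90, 20, 80, 10))
        assert m.sensitivity == pytest.approx(90.0)
        assert m.specificity == pytest.approx(80.0)
        assert m.accuracy == pytest.approx(85.0)
        assert m.ppv == pytest.approx(100 * 90 / 110)
        assert m.npv == pytest.approx(100 * 80 / 90)
        assert m.undefined == ()

    def test_perfect_classifier(self):
        m = tf.confusion_metrics(tf.ConfusionCounts(10, 0, 10, 0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) \
            == (100, 100, 100, 100, 100)

    def test_degenerate_all_false_negative(self):
        m = tf.confusion_metrics(tf.ConfusionCounts(0, 0, 0, 5))
        assert m.sensitivity == 0.0
        assert m.npv == 0.0
        assert math.isnan(m.ppv) and math.isnan(m.specificity)
        assert set(m.undefined) == {"ppv", "specificity"}

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            tf.confusion_metrics(tf.ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ValueError):
            tf.ConfusionCounts(-1, 0, 0, 5)

    def test_exhaustive_agreement_with_defining_ratios(self):
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            m = tf.confusion_metrics(tf.ConfusionCounts(tp, fp, tn, fn))
            ref = confusion_bruteforce(tp, fp, tn, fn)
            for name, value in ref.items():
                got = getattr(m, name)
                assert (math.isnan(got) and math.isnan(value)) \
                    or got == pytest.approx(value)

    def test_accuracy_decomposition_identity(self):
        # accuracy = (sens*P + spec*N) / (P + N)
        for tp, fp, tn, fn in itertools.product(range(1, 5), repeat=4):
            m = tf.confusion_metrics(tf.ConfusionCounts(tp, fp, tn, fn))
            P, N = tp + fn, tn + fp
            assert m.accuracy == pytest.approx(
                (m.sensitivity * P + m.specificity * N) / (P + N))


class TestRocAuc:
    def test_perfect_separation(self):
        assert tf.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_example_three_of_four_pairs(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert tf.roc_auc(scores, labels) == pytest.approx(0.75)
        assert auc_pairs(scores, labels) == pytest.approx(0.75)

    def test_chance_level_for_independent_scores(self, rng):
        scores = rng.uniform(0, 1, 4000)
        labels = rng.integers(0, 2, 4000)
        assert tf.roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 4, n).astype(float)  # ties likely
            assert tf.roc_auc(scores, labels) == pytest.approx(
                auc_pairs(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tf.roc_auc([0.2, 0.4], [1, 1])


def _separable_features(rng, n_per_class=40, gap=4.0):
    X0 = rng.normal(0, 1, (n_per_class, 5))
    X1 = rng.normal(gap, 1, (n_per_class, 5))
    X = np.vstack([X0, X1])
    y = np.array(["normal"] * n_per_class + ["diabetes"] * n_per_class)
    return pd.DataFrame(X), y


class TestTrainEval:
    def test_separated_classes_classified_accurately(self, rng):
        X, y = _separable_features(rng)
        reports = tf.train_eval(X, y, seed=1, modality="fused")
        assert {r.classifier_name for r in reports} == {"SVM", "LDA", "k-NN"}
        for r in reports:
            assert r.accuracy >= 85.0
            assert r.auc >= 0.9
            assert r.counts.total == r.n_test

    def test_permuted_labels_near_chance(self, rng):
        X0 = rng.normal(0, 1, (150, 5))
        y = np.array(["normal", "diabetes"] * 75)
        accs = [r.accuracy for r in tf.train_eval(pd.DataFrame(X0), y,
                                                  seed=2)]
        for acc in accs:
            assert 20.0 <= acc <= 80.0  # chance band on a 22-item test split

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = _separable_features(rng)
        a = tf.train_eval(X, y, seed=3)
        b = tf.train_eval(X, y, seed=3)
        assert [r.as_dict() for r in a] == [r.as_dict() for r in b]

    def test_degenerate_split_rejected(self, rng):
        X, y = _separable_features(rng, n_per_class=4)
        with pytest.raises(ValueError, match="degenerate"):
            tf.train_eval(X, y, seed=1)


class TestBlandAltman:
    def test_identical_series(self):
        res = tf.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0
        assert res.lower_loa == res.upper_loa == 0

    def test_constant_shift_has_zero_spread(self):
        a = np.array([34.1, 35.2, 36.0, 34.8])
        res = tf.bland_altman(a + 0.25, a)
        assert res.mean_difference == pytest.approx(0.25)
        assert res.lower_loa == pytest.approx(0.25)
        assert res.upper_loa == pytest.approx(0.25)

    def test_three_point_hand_example(self):
        res = tf.bland_altman([1.0, 1.2, 1.4], [1.0, 1.0, 1.0])
        assert res.mean_difference == pytest.approx(0.2)
        assert res.upper_loa == pytest.approx(0.2 + 1.96 * 0.2)
        assert res.lower_loa == pytest.approx(0.2 - 1.96 * 0.2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tf.bland_altman([1.0, 2.0], [1.0])


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = tf.group_comparison(table, ["normal"] * 3 + ["diabetes"] * 3)
        assert out.loc["v", "t_stat"] == pytest.approx(0.0)
        assert out.loc["v", "label"] == "NS"

    def test_printed_temperature_effect_is_detected(self):
        # both groups at the study's tongue-temperature moments, n=80:
        # the 1.54 degC effect is overwhelming at these sample sizes
        for seed in range(5):
            rng = np.random.default_rng(seed)
            temps = np.concatenate([rng.normal(34.32, 0.42, 80),
                                    rng.normal(35.86, 0.80, 80)])
            table = pd.DataFrame({"tongue_temp": temps})
            out = tf.group_comparison(
                table, ["normal"] * 80 + ["diabetes"] * 80)
            assert bool(out.loc["tongue_temp", "significant"])

    def test_zero_variance_equal_means_ns(self):
        table = pd.DataFrame({"v": [5.0] * 8})
        out = tf.group_comparison(table, ["normal"] * 4 + ["diabetes"] * 4)
        assert out.loc["v", "p_value"] == 1.0
        assert out.loc["v", "label"] == "NS"

    def test_cohort_table_report_shape(self):
        recs = tf.generate_cohort(tf.CohortConfig(n_per_group=30, seed=4))
        table = tf.cohort_table(recs)
        out = tf.group_comparison(table.drop(columns=["subject_id", "sex"]),
                                  table["group"])
        assert "tongue_temp" in out.index
        assert {"normal_mean", "diabetes_mean", "p_value"} <= set(out.columns)

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            tf.group_comparison(pd.DataFrame({"v": [1.0, 2.0, 3.0]}),
                                ["normal", "normal", "diabetes"])
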