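"""Metric panel, LOOCV integrity and the sequential two-stage system."""

import numpy as np
import pytest

from epiconnect.classify import (
    LoocvResult,
    SelectionConfig,
    SequentialClassifier,
    collapse_to_diagnosis,
    loocv,
    metric_panel,
    panel_from_counts,
    sequential_loocv,
    three_class_confusion,
    to_diagnosis_labels,
    train_balanced_rf,
)
from epiconnect.features import FeatureTable
from epiconnect.forest import BalancedForestSpec
from tests.conftest import make_noise_table


def _labelled_table(n_a=12, n_b=12, sd=0.1, seed=0, n_noise=3, labels=("A", "B")):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    labs = [labels[0]] * n_a + [labels[1]] * n_b
    signal = np.where(np.asarray(labs) == labels[0], 1.0, -1.0)
    values = np.column_stack([
        signal + sd * rng.standard_normal(n), rng.standard_normal((n, n_noise)),
    ])
    names = ["signal"] + [f"noise{j}" for j in range(n_noise)]
    return FeatureTable([f"s{i:02d}" for i in range(n)], names, values, labs)


class TestMetricPanel:
    def test_collapsed_confusion_counts(self):
        report = panel_from_counts(tp=38, fn=2, fp=5, tn=30)
        assert report.accuracy == 90.7
        assert report.sensitivity == 95.0
        assert report.specificity == 85.7
        assert report.ppv == 88.4
        assert report.npv == 93.8
        assert report.confusion.loc["TLE", "TLE"] == 38

    def test_perfect_predictions(self):
        actual = ["P"] * 5 + ["N"] * 5
        report = metric_panel(actual, actual, scores=[1.0] * 5 + [0.0] * 5,
                              positive_class="P")
        for value in (report.accuracy, report.sensitivity, report.specificity,
                      report.ppv, report.npv):
            assert value == 100.0
        assert report.auc == 1.0

    def test_constant_scores_auc_half(self):
        actual = ["P"] * 4 + ["N"] * 4
        predicted = ["P", "N"] * 4
        report = metric_panel(actual, predicted, scores=[0.5] * 8, positive_class="P")
        assert report.auc == 0.5

    def test_confusion_rows_sum_to_class_sizes(self):
        rng = np.random.default_rng(1)
        actual = np.where(rng.random(30) < 0.4, "P", "N")
        predicted = np.where(rng.random(30) < 0.5, "P", "N")
        report = metric_panel(actual, predicted, positive_class="P")
        assert report.confusion.loc["P"].sum() == int((actual == "P").sum())
        assert report.confusion.loc["N"].sum() == int((actual == "N").sum())
        acc = np.trace(report.confusion.to_numpy()) / len(actual)
        assert report.accuracy == round(100 * acc, 1)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="exactly two"):
            metric_panel(["P"] * 4, ["P"] * 4, positive_class="P")


class TestLoocv:
    def test_each_subject_predicted_once(self, small_spec):
        table = _labelled_table(seed=2)
        res = loocv(table, SelectionConfig(n_repeats=8), small_spec, seed=3,
                    positive_class="A")
        assert res.subject_ids == table.subject_ids
        assert len(res.predicted) == table.n_subjects
        assert len(res.fold_selections) == table.n_subjects

    def test_label_leak_gives_perfect_accuracy(self, small_spec):
        """A feature identical to the label is found in every fold."""
        table = _labelled_table(sd=0.01, seed=4)
        res = loocv(table, SelectionConfig(n_repeats=8), small_spec, seed=5,
                    positive_class="A")
        assert res.accuracy() == 1.0

    def test_holdout_only_feature_never_selected_in_its_fold(self, small_spec):
        """Leakage guard: a feature whose only information concerns the
        held-out subject cannot be selected in that subject's fold."""
        table = _labelled_table(n_a=10, n_b=10, seed=6)
        target = 0
        leak = np.zeros(table.n_subjects)
        leak[target] = 50.0  # informative about subject 0 only, noise elsewhere
        values = np.column_stack([table.values, leak])
        table2 = FeatureTable(table.subject_ids, table.feature_names + ["leak"],
                              values, table.labels)
        res = loocv(table2, SelectionConfig(n_repeats=8), small_spec, seed=7,
                    positive_class="A")
        assert "leak" not in res.fold_selections[target].selected

    def test_per_fold_selections_recorded_and_capped(self, small_spec):
        table = _labelled_table(n_a=15, n_b=15, seed=8)
        res = loocv(table, SelectionConfig(n_repeats=8), small_spec, seed=9,
                    positive_class="A")
        cap = 30 // 10
        for sel in res.fold_selections:
            assert 1 <= len(sel.selected) <= cap

    def test_too_few_subjects_rejected(self, small_spec):
        table = _labelled_table(n_a=1, n_b=1)
        with pytest.raises(ValueError, match="at least 3"):
            loocv(table, SelectionConfig(), small_spec, seed=0)


class TestSequentialSystem:
    def _three_group_table(self, n_per=8, sd=0.05, seed=10):
        """Separable synthetic three-group table: feature 0 separates TLE from
        CONTROL, feature 1 separates LTLE from RTLE."""
        rng = np.random.default_rng(seed)
        labels = ["CONTROL"] * n_per + ["LTLE"] * n_per + ["RTLE"] * n_per
        arr = np.asarray(labels)
        diag = np.where(arr == "CONTROL", -1.0, 1.0)
        lat = np.where(arr == "LTLE", 1.0, np.where(arr == "RTLE", -1.0, 0.0))
        n = len(labels)
        values = np.column_stack([
            diag + sd * rng.standard_normal(n),
            lat + sd * rng.standard_normal(n),
            rng.standard_normal((n, 3)),
        ])
        return FeatureTable([f"s{i:02d}" for i in range(n)],
                            ["diag_axis", "lat_axis", "n0", "n1", "n2"],
                            values, labels)

    def test_perfect_stages_give_diagonal_confusion(self, small_spec):
        table = self._three_group_table()
        seq = sequential_loocv(table, SelectionConfig(n_repeats=8), small_spec, seed=11)
        conf = seq.confusion.to_numpy()
        assert np.trace(conf) == table.n_subjects
        assert seq.overall_accuracy == 100.0

    def test_collapse_reproduces_diagnosis_confusion(self, small_spec):
        table = self._three_group_table(sd=0.8, seed=12)  # imperfect stages
        seq = sequential_loocv(table, SelectionConfig(n_repeats=8), small_spec, seed=13)
        collapsed = collapse_to_diagnosis(seq.confusion)
        diag_report = seq.diagnosis.report()
        np.testing.assert_array_equal(collapsed.to_numpy(),
                                      diag_report.confusion.to_numpy())

    def test_rows_sum_to_group_sizes(self, small_spec):
        table = self._three_group_table(sd=1.5, seed=14)
        seq = sequential_loocv(table, SelectionConfig(n_repeats=8), small_spec, seed=15)
        for group in ("LTLE", "RTLE", "CONTROL"):
            assert seq.confusion.loc[group].sum() == 8

    def test_control_short_circuits_lateralization(self, small_spec):
        """The lateralization stage is never invoked for a subject the
        diagnosis stage calls CONTROL."""
        table = self._three_group_table()
        labels = np.asarray(table.labels)
        diag_table = table.with_labels(to_diagnosis_labels(labels))
        diag_forest = train_balanced_rf(
            diag_table.restrict_features(["diag_axis"]), small_spec,
            positive_class="TLE", seed=16,
        )
        patients = table.restrict_subjects(labels != "CONTROL")
        lat_forest = train_balanced_rf(
            patients.restrict_features(["lat_axis"]), small_spec,
            positive_class="LTLE", seed=17,
        )
        clf = SequentialClassifier(diag_forest, ["diag_axis"], lat_forest,
                                   ["lat_axis"], table.feature_names)
        control_rows = table.values[labels == "CONTROL"]
        for row in control_rows:
            assert clf.predict_row(row) == "CONTROL"
        assert clf.lat_calls == 0
        patient_row = table.values[labels == "LTLE"][0]
        assert clf.predict_row(patient_row) == "LTLE"
        assert clf.lat_calls == 1

    def test_missing_required_feature_rejected(self, small_spec):
        table = self._three_group_table()
        labels = np.asarray(table.labels)
        diag_forest = train_balanced_rf(
            table.with_labels(to_diagnosis_labels(labels)).restrict_features(
                ["diag_axis"]
            ),
            small_spec, positive_class="TLE", seed=18,
        )
        with pytest.raises(KeyError, match="absent"):
            SequentialClassifier(diag_forest, ["diag_axis"], diag_forest,
                                 ["not_a_feature"], table.feature_names)


def test_three_class_confusion_structure():
    actual = ["LTLE", "RTLE", "CONTROL", "LTLE"]
    predicted = ["LTLE", "CONTROL", "CONTROL", "RTLE"]
    conf = three_class_confusion(actual, predicted)
    assert conf.loc["LTLE", "LTLE"] == 1
    assert conf.loc["LTLE", "RTLE"] == 1
    assert conf.loc["RTLE", "CONTROL"] == 1
    assert conf.to_numpy().sum() == 4
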