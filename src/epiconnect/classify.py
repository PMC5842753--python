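"""Leave-one-out evaluation, metric panel and the sequential two-stage system.

Every reported metric comes from a leave-one-out cross-validation in which the
held-out subject plays no part in feature selection or training of its fold:
screening, minimal-subset selection and forest training are all redone on the
remaining subjects.  The clinical system is sequential -- a subject is first
diagnosed (TLE vs control) and, only if diagnosed, lateralized (left vs right
TLE) -- so the three-class confusion matrix is assembled from two two-class
balanced forests applied in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import FeatureTable
from .forest import BalancedForestSpec, BalancedRandomForest
from .selection import SelectionResult, feature_cap, screen_and_select

DIAGNOSIS_POSITIVE = "TLE"
LATERALIZATION_POSITIVE = "LTLE"


@dataclass
class SelectionConfig:
    """Per-fold feature-selection settings used inside LOOCV."""

    alpha: float = 0.05
    n_repeats: int = 50
    tol_se: float = 1.0
    cap: int | None = None  # None -> floor(n_cohort / 10)
    significance: str = "zscore"
    redundancy_r: float | None = 0.8


@dataclass
class ClassifierReport:
    """Metric panel of one two-class classifier.

    Percentages are rounded to one decimal at this reporting layer only;
    ``confusion`` is actual x predicted with the positive class first.
    """

    positive_class: object
    negative_class: object
    confusion: pd.DataFrame
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float | None

    def to_dict(self) -> dict:
        return {
            "positive_class": str(self.positive_class),
            "negative_class": str(self.negative_class),
            "confusion": {
                str(a): {str(p): int(v) for p, v in row.items()}
                for a, row in self.confusion.to_dict(orient="index").items()
            },
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "auc": self.auc,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Accuracy (%)", self.accuracy),
            ("Sensitivity (%)", self.sensitivity),
            ("Specificity (%)", self.specificity),
            ("Positive predictive val. (%)", self.ppv),
            ("Negative predictive val. (%)", self.npv),
            ("AUC", self.auc),
        ]
        return pd.DataFrame(rows, columns=["Performance measure", "value"])


def _pct(num: float, den: float) -> float:
    return round(100.0 * num / den, 1)


def metric_panel(actual, predicted, scores=None, positive_class=None) -> ClassifierReport:
    """Standard 2x2 diagnostic panel from per-subject predictions.

    ``scores`` (positive-class vote fractions) feed the rank-statistic AUC;
    without them AUC is omitted.  Raises if either class is absent from
    ``actual`` (the denominators would be undefined).
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    classes = sorted(set(actual.tolist()) | set(predicted.tolist()))
    if len(classes) != 2:
        raise ValueError(f"metric panel needs exactly two classes, got {classes}")
    pos = positive_class if positive_class is not None else classes[-1]
    if pos not in classes:
        raise ValueError(f"positive_class {pos!r} not among labels {classes}")
    neg = classes[0] if classes[1] == pos else classes[1]
    if not (actual == pos).any() or not (actual == neg).any():
        raise ValueError("both classes must be present in the actual labels")

    tp = int(np.sum((actual == pos) & (predicted == pos)))
    fn = int(np.sum((actual == pos) & (predicted != pos)))
    fp = int(np.sum((actual != pos) & (predicted == pos)))
    tn = int(np.sum((actual != pos) & (predicted != pos)))
    confusion = pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=pd.Index([pos, neg], name="actual"),
        columns=pd.Index([pos, neg], name="predicted"),
    )
    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        auc = float(roc_auc_score((actual == pos).astype(int), scores))
    return ClassifierReport(
        positive_class=pos,
        negative_class=neg,
        confusion=confusion,
        accuracy=_pct(tp + tn, tp + tn + fp + fn),
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        ppv=_pct(tp, tp + fp),
        npv=_pct(tn, tn + fn),
        auc=auc,
    )


def panel_from_counts(tp: int, fn: int, fp: int, tn: int,
                      positive_class="TLE", negative_class="CONTROL") -> ClassifierReport:
    """Metric panel computed from 2x2 confusion counts (no AUC)."""
    actual = [positive_class] * (tp + fn) + [negative_class] * (fp + tn)
    predicted = (
        [positive_class] * tp + [negative_class] * fn
        + [positive_class] * fp + [negative_class] * tn
    )
    return metric_panel(actual, predicted, positive_class=positive_class)


def train_balanced_rf(
    table: FeatureTable,
    spec: BalancedForestSpec | None = None,
    positive_class=None,
    seed: int | None = None,
) -> BalancedRandomForest:
    """Fit a balanced forest on a two-class feature table."""
    forest = BalancedRandomForest(spec, positive_class=positive_class)
    forest.fit(table.values, np.asarray(table.labels), seed=seed)
    return forest


@dataclass
class LoocvResult:
    """Per-subject LOOCV predictions with the per-fold selection trail."""

    subject_ids: list
    actual: list
    predicted: list
    scores: np.ndarray  # positive-class vote fraction per held-out subject
    positive_class: object
    fold_selections: list = field(default_factory=list)  # SelectionResult per fold

    def report(self) -> ClassifierReport:
        return metric_panel(self.actual, self.predicted, self.scores,
                            positive_class=self.positive_class)

    def accuracy(self) -> float:
        return float(np.mean(np.asarray(self.actual) == np.asarray(self.predicted)))


def loocv(
    table: FeatureTable,
    selection: SelectionConfig | None = None,
    forest_spec: BalancedForestSpec | None = None,
    seed: int = 0,
    positive_class=None,
) -> LoocvResult:
    """Leave-one-out evaluation with the selection pipeline redone per fold.

    The cap follows the one-feature-per-ten-subjects rule computed on the
    cohort entering the cross-validation and is held fixed across folds.
    """
    selection = selection or SelectionConfig()
    n = table.n_subjects
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    labels = np.asarray(table.labels)
    if len(set(labels.tolist())) != 2:
        raise ValueError("LOOCV classifier needs exactly two classes")
    cap = selection.cap if selection.cap is not None else feature_cap(n)

    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=(n, 2))
    predicted, scores, selections = [], [], []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = table.restrict_subjects(keep)
        if len(set(train.labels)) < 2:
            raise ValueError(f"fold {i}: training set became single-class")
        sel, _ = screen_and_select(
            train,
            forest_spec,
            cap=cap,
            alpha=selection.alpha,
            n_repeats=selection.n_repeats,
            tol_se=selection.tol_se,
            seed=int(fold_seeds[i, 0]),
            positive_class=positive_class,
            significance=selection.significance,
            redundancy_r=selection.redundancy_r,
        )
        forest = train_balanced_rf(
            train.restrict_features(sel.selected),
            forest_spec,
            positive_class=positive_class,
            seed=int(fold_seeds[i, 1]),
        )
        row = table.restrict_features(sel.selected).values[i]
        frac = float(forest.vote_fractions(row)[0])
        neg, pos = forest.classes_
        predicted.append(pos if frac >= 0.5 else neg)
        scores.append(frac)
        selections.append(sel)

    pos = positive_class if positive_class is not None else sorted(set(labels))[-1]
    return LoocvResult(
        subject_ids=list(table.subject_ids),
        actual=list(table.labels),
        predicted=predicted,
        scores=np.asarray(scores),
        positive_class=pos,
        fold_selections=selections,
    )


# ---------------------------------------------------------------------------
# Sequential two-classifier system: diagnose, then lateralize.
# ---------------------------------------------------------------------------

THREE_CLASS_ORDER = ("LTLE", "RTLE", "CONTROL")


def to_diagnosis_labels(group_labels) -> list:
    """Collapse three-group labels to TLE vs CONTROL."""
    return ["CONTROL" if g == "CONTROL" else "TLE" for g in group_labels]


class SequentialClassifier:
    """Diagnosis stage, then lateralization stage (only if diagnosed).

    Each stage owns its forest and its selected feature subset.  The
    lateralization stage is never consulted for a subject the diagnosis stage
    labels CONTROL; ``lat_calls`` counts actual stage-2 invocations.
    """

    def __init__(self, diag_forest, diag_features, lat_forest, lat_features,
                 feature_names):
        self.diag_forest = diag_forest
        self.diag_features = list(diag_features)
        self.lat_forest = lat_forest
        self.lat_features = list(lat_features)
        self._index = {name: i for i, name in enumerate(feature_names)}
        for f in self.diag_features + self.lat_features:
            if f not in self._index:
                raise KeyError(f"classifier requires feature {f!r} absent from the table")
        self.lat_calls = 0

    def _take(self, row: np.ndarray, names) -> np.ndarray:
        return np.asarray([row[self._index[f]] for f in names], dtype=float)

    def predict_row(self, row) -> str:
        row = np.asarray(row, dtype=float)
        diag = self.diag_forest.predict(self._take(row, self.diag_features))[0]
        if diag == "CONTROL":
            return "CONTROL"
        self.lat_calls += 1
        return str(self.lat_forest.predict(self._take(row, self.lat_features))[0])


@dataclass
class SequentialReport:
    """Three-class LOOCV outcome of the sequential system."""

    subject_ids: list
    actual: list
    predicted: list
    confusion: pd.DataFrame  # rows/cols in THREE_CLASS_ORDER
    overall_accuracy: float  # percent, 1 decimal
    diagnosis: LoocvResult
    lateralization: LoocvResult  # standalone LOOCV on the patients

    def to_dict(self) -> dict:
        return {
            "overall_accuracy_pct": self.overall_accuracy,
            "confusion": {
                a: {p: int(v) for p, v in row.items()}
                for a, row in self.confusion.to_dict(orient="index").items()
            },
            "predicted": dict(zip(map(str, self.subject_ids), self.predicted)),
        }


def three_class_confusion(actual, predicted) -> pd.DataFrame:
    conf = pd.DataFrame(
        0,
        index=pd.Index(THREE_CLASS_ORDER, name="actual"),
        columns=pd.Index(THREE_CLASS_ORDER, name="predicted"),
    )
    for a, p in zip(actual, predicted):
        conf.loc[a, p] += 1
    return conf


def collapse_to_diagnosis(confusion: pd.DataFrame) -> pd.DataFrame:
    """Collapse the LTLE/RTLE rows and columns of a three-class confusion
    matrix into a single TLE class, giving the diagnosis-stage 2x2 matrix."""
    tle = ["LTLE", "RTLE"]
    tp = int(confusion.loc[tle, tle].to_numpy().sum())
    fn = int(confusion.loc[tle, "CONTROL"].sum())
    fp = int(confusion.loc["CONTROL", tle].sum())
    tn = int(confusion.loc["CONTROL", "CONTROL"])
    return pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=pd.Index(["TLE", "CONTROL"], name="actual"),
        columns=pd.Index(["TLE", "CONTROL"], name="predicted"),
    )


def sequential_loocv(
    table: FeatureTable,
    selection: SelectionConfig | None = None,
    forest_spec: BalancedForestSpec | None = None,
    seed: int = 0,
) -> SequentialReport:
    """LOOCV of the full three-class system on a three-group feature table.

    The diagnosis stage is an LOOCV over all subjects (TLE vs CONTROL); the
    lateralization stage reuses the standalone patients-only LOOCV for
    patient folds, and for control subjects a single lateralization model
    trained on all patients (their folds never exclude a patient).
    """
    labels = np.asarray(table.labels)
    if not set(labels.tolist()) <= set(THREE_CLASS_ORDER):
        raise ValueError(f"labels must be among {THREE_CLASS_ORDER}")
    selection = selection or SelectionConfig()
    rng = np.random.default_rng(seed)
    s_diag, s_lat, s_latall = (int(v) for v in rng.integers(0, 2**31 - 1, size=3))

    diag_table = table.with_labels(to_diagnosis_labels(labels))
    diag_res = loocv(diag_table, selection, forest_spec, seed=s_diag,
                     positive_class=DIAGNOSIS_POSITIVE)

    patient_mask = labels != "CONTROL"
    patients = table.restrict_subjects(patient_mask)
    lat_res = loocv(patients, selection, forest_spec, seed=s_lat,
                    positive_class=LATERALIZATION_POSITIVE)

    # one lateralization model over all patients, for the control folds
    sel_all, _ = screen_and_select(
        patients, forest_spec,
        cap=selection.cap if selection.cap is not None else feature_cap(patients.n_subjects),
        alpha=selection.alpha, n_repeats=selection.n_repeats,
        tol_se=selection.tol_se, seed=s_latall,
        positive_class=LATERALIZATION_POSITIVE, significance=selection.significance,
        redundancy_r=selection.redundancy_r,
    )
    lat_all = train_balanced_rf(
        patients.restrict_features(sel_all.selected), forest_spec,
        positive_class=LATERALIZATION_POSITIVE, seed=s_latall,
    )

    lat_pred_by_sid = dict(zip(lat_res.subject_ids, lat_res.predicted))
    predicted = []
    for i, sid in enumerate(table.subject_ids):
        if diag_res.predicted[i] == "CONTROL":
            predicted.append("CONTROL")
        elif labels[i] != "CONTROL":
            predicted.append(lat_pred_by_sid[sid])
        else:
            row = table.restrict_features(sel_all.selected).values[i]
            predicted.append(str(lat_all.predict(row)[0]))

    conf = three_class_confusion(labels, predicted)
    overall = round(100.0 * np.trace(conf.to_numpy()) / len(labels), 1)
    return SequentialReport(
        subject_ids=list(table.subject_ids),
        actual=labels.tolist(),
        predicted=predicted,
        confusion=conf,
        overall_accuracy=overall,
        diagnosis=diag_res,
        lateralization=lat_res,
    )
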