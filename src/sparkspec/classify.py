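"""Leave-one-patient-out training and evaluation of a margin-based binary
classifier with per-patient diagnostic metrics.

Positive class is ``abnormal``. Each fold standardizes features on its
training rows only and fits an RBF support-vector classifier; metrics with a
zero denominator are reported as NaN and skipped when averaging over
patients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from sparkspec.features import FeatureMatrix

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "abnormal"
NEGATIVE_LABEL = "normal"

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class SVCParams:
    """Classifier hyperparameters; defaults give reproducible runs."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    class_weight: str | None = None


@dataclass
class SplitPlan:
    """One fold per patient: that patient's rows are the test set."""

    folds: list[tuple[str, np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """The five diagnostic metrics; NaN where the denominator is zero."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


@dataclass
class MetricsReport:
    """Per-patient confusion counts and metrics plus their arithmetic means
    over patients (NaN entries skipped)."""

    per_patient: list[tuple[str, ConfusionCounts, dict[str, float]]]
    mean: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            self.mean = {}
            for m in METRIC_NAMES:
                vals = [
                    met[m]
                    for _, _, met in self.per_patient
                    if not math.isnan(met[m])
                ]
                self.mean[m] = sum(vals) / len(vals) if vals else math.nan

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"patient_id": pid, **{m: met[m] for m in METRIC_NAMES}}
            for pid, _, met in self.per_patient
        ]
        rows.append({"patient_id": "mean", **self.mean})
        return pd.DataFrame(rows, columns=["patient_id", *METRIC_NAMES])


def make_splits(matrix: FeatureMatrix) -> SplitPlan:
    """Deterministic leave-one-patient-out folds, sorted by patient id."""
    patients = sorted(set(matrix.patient_ids))
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    all_rows = np.arange(matrix.n_rows)
    folds = []
    for pid in patients:
        test = all_rows[matrix.patient_ids == pid]
        train = all_rows[matrix.patient_ids != pid]
        folds.append((pid, train, test))
    return SplitPlan(folds=folds)


def fit(train: FeatureMatrix, params: SVCParams = SVCParams()) -> Pipeline:
    """Standardize on the training rows only, then fit the SVC."""
    classes = set(train.labels)
    if len(classes) < 2:
        raise ValueError(f"training set has a single class {classes}")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    C=params.C,
                    kernel=params.kernel,
                    gamma=params.gamma,
                    class_weight=params.class_weight,
                ),
            ),
        ]
    )
    model.fit(train.values, train.labels.astype(str))
    return model


def predict(model: Pipeline, test: FeatureMatrix) -> list[str]:
    if test.n_rows == 0:
        return []
    n_expected = model.named_steps["scale"].n_features_in_
    if test.values.shape[1] != n_expected:
        raise ValueError(
            f"feature count mismatch: model expects {n_expected}, "
            f"got {test.values.shape[1]}"
        )
    return [str(l) for l in model.predict(test.values)]


def evaluate(labels_true, labels_pred) -> ConfusionCounts:
    """Confusion counts with positive class = abnormal."""
    labels_true = list(labels_true)
    labels_pred = list(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors differ in length")
    tp = fp = tn = fn = 0
    for t, p in zip(labels_true, labels_pred):
        if t not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"unknown true label {t!r}")
        if p not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"unknown predicted label {p!r}")
        if t == POSITIVE_LABEL:
            if p == POSITIVE_LABEL:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE_LABEL:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def run_lopo(
    matrix: FeatureMatrix, params: SVCParams = SVCParams()
) -> tuple[MetricsReport, pd.DataFrame]:
    """Fit and evaluate every leave-one-patient-out fold.

    Returns the metrics report and a per-spectrum prediction table. A
    structural no-leakage assertion (no training row carries the test
    patient id) runs on every fold.
    """
    plan = make_splits(matrix)
    per_patient = []
    pred_rows = []
    n_undefined = 0
    for pid, train_idx, test_idx in plan.folds:
        assert not np.any(matrix.patient_ids[train_idx] == pid), (
            f"leakage: fold {pid} has test-patient rows in training"
        )
        train = matrix.subset(train_idx)
        test = matrix.subset(test_idx)
        try:
            model = fit(train, params)
            preds = predict(model, test)
        except ValueError as exc:
            raise ValueError(f"fold {pid}: {exc}") from exc
        counts = evaluate(test.labels, preds)
        metrics = metrics_from_counts(counts)
        n_undefined += sum(1 for v in metrics.values() if math.isnan(v))
        per_patient.append((pid, counts, metrics))
        for sid, t, p in zip(test.spectrum_ids, test.labels, preds):
            pred_rows.append(
                {
                    "spectrum_id": sid,
                    "patient_id": pid,
                    "true_label": t,
                    "predicted_label": p,
                }
            )
    if n_undefined:
        logger.info(
            "run_lopo: %d undefined metric entries skipped in means", n_undefined
        )
    report = MetricsReport(per_patient=per_patient)
    predictions = pd.DataFrame(
        pred_rows,
        columns=["spectrum_id", "patient_id", "true_label", "predicted_label"],
    )
    return report, predictions
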