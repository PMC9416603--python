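"""Classifier benchmarking under stratified five-fold cross-validation.

Extracted features (learned or manual) are scored with four standard
classifiers — RBF-kernel SVM (C=1), KNN (k=5), a Gini decision tree and a
100-tree random forest — under seeded stratified 5-fold CV with per-fold
z-scoring fit on the training folds only.  The comparison grid covers the
standard condition codes:

    ISL / ESL / IESL   single-stream CNN features from IMU / EMG / the
                       channel-stacked fusion of both
    IEDL               dual-stream CNN features filtered by ReliefF
    ITD/IFD/ITF, ETD/EFD/ETF and their "+" fusions
                       manual time/frequency feature conditions

Fold assignment depends only on (labels, seed), so every condition is
scored on identical folds and comparisons are paired.  The CNN extractor is
fit on the 70% train split (with the 10% validation split for monitoring)
and the CV runs over the union of its train and test windows; the extractor
having seen the CV-training windows makes the accuracies optimistic
relative to a fully nested design — a deliberate, documented property of
the protocol rather than an oversight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cnn import DualStreamCNN, SingleStreamCNN, extract
from .features import FeatureMatrix, extract_manual
from .preprocess import WindowSet
from .relieff import ReliefF, select

CLASSIFIERS = ("SVM", "KNN", "DT", "RF")
CNN_CONDITIONS = ("ISL", "ESL", "IESL", "IEDL")


@dataclass
class CVConfig:
    """Five seeded stratified folds with per-fold standardization."""

    folds: int = 5
    stratified: bool = True
    seed: int = 0
    standardize: bool = True


@dataclass
class EvaluationReport:
    """Per-fold accuracies, their mean, and the fold-summed confusion
    matrix for one (condition, classifier) cell."""

    condition: str
    classifier: str
    fold_accuracies: list[float]
    confusion: np.ndarray
    subject: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "classifier": self.classifier,
            "subject": self.subject,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "extra": self.extra,
        }

    @staticmethod
    def from_dict(d: dict) -> "EvaluationReport":
        return EvaluationReport(
            condition=d["condition"], classifier=d["classifier"],
            fold_accuracies=list(d["fold_accuracies"]),
            confusion=np.asarray(d["confusion"]),
            subject=d.get("subject"), extra=d.get("extra", {}),
        )


def make_classifier(kind: str, seed: int = 0):
    """Documented default hyperparameters for the four families."""
    kind = kind.upper()
    if kind == "SVM":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if kind == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if kind == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; expected "
                     f"{CLASSIFIERS}")


def cross_validate(X, y, kind: str, cv: CVConfig | None = None,
                   condition: str = "", subject: str | None = None
                   ) -> EvaluationReport:
    """Stratified k-fold CV accuracy of one classifier on one feature set.

    Standardization (when enabled) is fit on the training folds only, so no
    test-fold statistics leak into the model.  Raises if stratification
    cannot put every class in every fold.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cv.folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has fewer members "
            f"({counts.min()}) than folds ({cv.folds}); stratification "
            "would leave it absent from some fold")
    skf = StratifiedKFold(n_splits=cv.folds, shuffle=True,
                          random_state=cv.seed)
    accs, confs = [], []
    for tr, te in skf.split(X, y):
        clf = make_classifier(kind, seed=cv.seed)
        model = (make_pipeline(StandardScaler(), clf) if cv.standardize
                 else clf)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        accs.append(float(np.mean(pred == y[te])))
        confs.append(confusion_matrix(y[te], pred, labels=classes))
    return EvaluationReport(condition=condition, classifier=kind.upper(),
                            fold_accuracies=accs,
                            confusion=np.sum(confs, axis=0),
                            subject=subject)


# ---------------------------------------------------------------------------
# Condition grid
# ---------------------------------------------------------------------------

def condition_features(ws: WindowSet, condition: str, epochs: int = 30,
                       seed: int = 0, relieff_threshold: float = 0.1,
                       relieff_k: int = 10) -> FeatureMatrix:
    """Compute the feature matrix of one condition over the union of the
    train and test splits of `ws` (the rows the CV is run on).

    CNN conditions train their extractor on the train split (validation
    split monitored); IEDL additionally fits ReliefF on the extracted
    features and drops columns below the weight threshold.  Any other code
    is interpreted as a manual-feature condition (possibly a "+" fusion).
    """
    eval_ws = ws.split_subset("train", "test")
    if condition in CNN_CONDITIONS:
        tr = ws.split_subset("train")
        va = ws.split_subset("val")
        if len(tr) == 0:
            raise ValueError("window set has no train split; call split() first")
        val = (va.as_matrix(), va.labels) if len(va) else None
        if condition == "IEDL":
            model = DualStreamCNN(epochs=epochs, random_state=seed)
        else:
            modality = {"ISL": "imu", "ESL": "emg", "IESL": "fused"}[condition]
            model = SingleStreamCNN(modality=modality, epochs=epochs,
                                    random_state=seed)
        model.fit(tr.as_matrix(), tr.labels, validation_data=val)
        # every CNN condition is extracted at its pre-FC tap (the features
        # before the fully connected layer: 160 per single branch, 320 for
        # the fused and dual-stream variants); ReliefF pruning of that set
        # is what distinguishes the dual-stream-plus-ReliefF condition
        fm = extract(model, eval_ws, tap="fusion320")
        if condition == "IEDL":
            sel = ReliefF(n_neighbors=relieff_k, threshold=relieff_threshold,
                          random_state=seed)
            sel.fit(fm.values, fm.labels)
            fm = select(fm, sel)
        return fm
    return extract_manual(eval_ws, condition)


def run_comparison(ws: WindowSet, conditions: list[str],
                   classifiers: tuple[str, ...] = CLASSIFIERS,
                   cv: CVConfig | None = None, epochs: int = 30,
                   seed: int = 0) -> list[EvaluationReport]:
    """One report per (condition, classifier), on identical folds."""
    cv = cv or CVConfig(seed=seed)
    reports = []
    for condition in conditions:
        fm = condition_features(ws, condition, epochs=epochs, seed=seed)
        for kind in classifiers:
            rep = cross_validate(fm.values, fm.labels, kind, cv,
                                 condition=condition)
            rep.extra["n_features"] = len(fm.feature_names)
            reports.append(rep)
    return reports


def per_subject_eval(ws: WindowSet, condition: str = "IEDL",
                     classifiers: tuple[str, ...] = CLASSIFIERS,
                     epochs: int = 30, seed: int = 0,
                     cv: CVConfig | None = None,
                     split_seed: int = 0) -> pd.DataFrame:
    """Within-subject evaluation: per subject, fit the extractor on that
    subject's train split, extract, and run five-fold CV per classifier.

    Returns a table with one row per subject, one column per classifier
    plus their row average — and a final row of per-classifier means.
    """
    from .preprocess import split as split_windows

    subjects = list(dict.fromkeys(ws.subject))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    cv = cv or CVConfig(seed=seed)
    rows = {}
    for subject in subjects:
        sub = ws.subset(ws.subject == subject)
        if len(np.unique(sub.labels)) < 2:
            raise ValueError(f"subject {subject} has a single class")
        if np.all(sub.split == "unassigned"):
            sub = split_windows(sub, seed=split_seed)
        fm = condition_features(sub, condition, epochs=epochs, seed=seed)
        accs = [cross_validate(fm.values, fm.labels, kind, cv,
                               condition=condition,
                               subject=subject).mean_accuracy
                for kind in classifiers]
        rows[subject] = accs + [float(np.mean(accs))]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(classifiers) + ["Average"])
    table.loc["Mean"] = table.mean(axis=0)
    return table


# ---------------------------------------------------------------------------
# Serialization and visualization export
# ---------------------------------------------------------------------------

def save_reports(reports: list[EvaluationReport], path) -> None:
    with open(path, "w") as f:
        json.dump([r.to_dict() for r in reports], f, indent=1)


def load_reports(path) -> list[EvaluationReport]:
    with open(path) as f:
        return [EvaluationReport.from_dict(d) for d in json.load(f)]


def reports_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Condition x classifier mean-accuracy table."""
    df = pd.DataFrame([(r.condition, r.classifier, r.mean_accuracy)
                       for r in reports],
                      columns=["condition", "classifier", "accuracy"])
    return df.pivot(index="condition", columns="classifier",
                    values="accuracy")


def visualization_coords(fm: FeatureMatrix, selector: ReliefF) -> pd.DataFrame:
    """3-D scatter coordinates: the three highest-weighted features."""
    top = np.argsort(-selector.weights_)[:3]
    if len(top) < 3:
        raise ValueError("need at least three features to visualize")
    return pd.DataFrame({
        "window": np.arange(len(fm)),
        "x": fm.values[:, top[0]],
        "y": fm.values[:, top[1]],
        "z": fm.values[:, top[2]],
        "label": fm.labels,
    })
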