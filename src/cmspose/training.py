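"""Classifier bank: reference augmentation, oversampling, PCA + grid search.

Each CMS item (external-rotation items, internal rotation, strength) gets
its own classifier chosen from six families — logistic regression,
k-nearest neighbors, decision tree, support vector machine, random forest
and adaptive boosting.  The fitting pipeline is median imputation (missing
angle sentinels) -> PCA retaining a configured variance fraction (default
0.95) -> classifier, tuned by grid search under stratified k-fold
cross-validation (default 5 folds).  PCA and the grid refit inside every
fold's training split, so cross-validated accuracy is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_FAMILIES = (
    "logistic_regression",
    "knn",
    "decision_tree",
    "svm",
    "random_forest",
    "adaboost",
)

#: small default grids; the clinically relevant ranges, configurable per run.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"clf__C": [0.1, 1.0, 10.0]},
    "knn": {"clf__n_neighbors": [3, 5, 7, 9]},
    "decision_tree": {"clf__max_depth": [3, 5, 10, None]},
    "svm": {"clf__C": [0.1, 1.0, 10.0], "clf__kernel": ["rbf", "linear"]},
    "random_forest": {"clf__n_estimators": [100, 300]},
    "adaboost": {
        "clf__n_estimators": [50, 100, 200],
        "clf__estimator__max_depth": [3, 5],
    },
}


class SchemaMismatchError(ValueError):
    pass


@dataclass
class TrainingDataset:
    """Feature matrix + labels + per-row provenance.

    Provenance is one of {patient, positive_reference, negative_reference,
    oversampled} per row; totals reconcile against the augmentation log.
    """

    X: pd.DataFrame
    y: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.provenance is None:
            self.provenance = np.full(len(self.y), "patient", dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if not (len(self.X) == len(self.y) == len(self.provenance)):
            raise ValueError("X, y and provenance must have equal lengths")

    @property
    def n(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def provenance_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.provenance, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def augment_with_references(
    patient_data: TrainingDataset,
    positive: TrainingDataset | None = None,
    negative: TrainingDataset | None = None,
    use_positive: bool = True,
    use_negative: bool = True,
) -> TrainingDataset:
    """Row-concatenate healthy-volunteer (positive) and severely-impaired
    (negative) reference exemplars onto the patient data, tagging provenance.
    """
    parts_X = [patient_data.X]
    parts_y = [patient_data.y]
    parts_p = [patient_data.provenance]
    for data, tag, use in (
        (positive, "positive_reference", use_positive),
        (negative, "negative_reference", use_negative),
    ):
        if not (use and data is not None and data.n):
            continue
        if list(data.X.columns) != list(patient_data.X.columns):
            diff = set(data.X.columns) ^ set(patient_data.X.columns)
            raise SchemaMismatchError(f"feature schema mismatch; differing columns: {sorted(diff)[:8]}")
        parts_X.append(data.X)
        parts_y.append(data.y)
        parts_p.append(np.full(data.n, tag, dtype=object))
    return TrainingDataset(
        pd.concat(parts_X, ignore_index=True),
        np.concatenate(parts_y),
        np.concatenate(parts_p),
    )


def oversample_minority(d: TrainingDataset, seed: int) -> TrainingDataset:
    """Random oversampling: duplicate minority-class rows with replacement
    until every class count equals the majority count.  Seeded; duplicates
    are tagged 'oversampled'.  Never creates new distinct feature rows.
    """
    counts = d.class_counts()
    if len(counts) < 2:
        raise ValueError("oversampling requires at least 2 classes")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    extra_idx: list[int] = []
    for cls in sorted(counts):
        deficit = target - counts[cls]
        if deficit:
            pool = np.flatnonzero(d.y == cls)
            extra_idx.extend(rng.choice(pool, size=deficit, replace=True).tolist())
    if not extra_idx:
        return d
    X = pd.concat([d.X, d.X.iloc[extra_idx]], ignore_index=True)
    y = np.concatenate([d.y, d.y[extra_idx]])
    prov = np.concatenate([d.provenance, np.full(len(extra_idx), "oversampled", dtype=object)])
    return TrainingDataset(X, y, prov)


def _make_estimator(family: str, seed: int):
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "svm":
        return SVC(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "adaboost":
        # depth-3 weak learner: decision stumps cannot express multi-class
        # boundaries, so boosting them stalls on 5-6 class tasks
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=seed),
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


@dataclass
class TrainedClassifier:
    """A fitted imputer->PCA->classifier pipeline with its CV report."""

    family: str
    pipeline: Pipeline
    best_params: dict
    cv_accuracy: float
    fold_accuracies: np.ndarray
    feature_columns: list[str]
    classes: np.ndarray
    seed: int

    def predict(self, features) -> np.ndarray:
        """Predict one task-legal label per instance."""
        if isinstance(features, pd.DataFrame):
            if list(features.columns) != self.feature_columns:
                raise SchemaMismatchError("prediction feature schema differs from training schema")
            X = features.to_numpy(float)
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
            if X.shape[1] != len(self.feature_columns):
                raise SchemaMismatchError(
                    f"expected {len(self.feature_columns)} features, got {X.shape[1]}"
                )
        return self.pipeline.predict(X)

    def save(self, directory: str | Path) -> Path:
        """Persist as a model bundle directory (parameters + manifest)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, directory / "model.joblib")
        manifest = {
            "family": self.family,
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
            "cv_accuracy": self.cv_accuracy,
            "seed": self.seed,
            "n_features": len(self.feature_columns),
        }
        import json

        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return directory

    @staticmethod
    def load(directory: str | Path) -> "TrainedClassifier":
        return joblib.load(Path(directory) / "model.joblib")


def fit_pipeline(
    d: TrainingDataset,
    family: str,
    grid: dict | None = None,
    variance_retained: float = 0.95,
    folds: int = 5,
    seed: int = 0,
) -> TrainedClassifier:
    """Grid-search a PCA+classifier pipeline under stratified k-fold CV.

    Ties between grid points resolve to the first point in declared order.
    Raises a stratification error when any class has fewer rows than folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")
    grid = dict(DEFAULT_GRIDS[family]) if grid is None else grid
    min_count = min(d.class_counts().values())
    if min_count < folds:
        raise ValueError(
            f"a class has only {min_count} rows (< {folds} folds); "
            "oversample the minority class or reduce folds"
        )
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("pca", PCA(n_components=variance_retained, svd_solver="full", random_state=seed)),
            ("clf", _make_estimator(family, seed)),
        ]
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, scoring="accuracy", cv=cv, refit=True, n_jobs=1)
    X = d.X.to_numpy(float)
    search.fit(X, d.y)
    i = search.best_index_
    fold_acc = np.array(
        [search.cv_results_[f"split{k}_test_score"][i] for k in range(folds)]
    )
    return TrainedClassifier(
        family=family,
        pipeline=search.best_estimator_,
        best_params=search.best_params_,
        cv_accuracy=float(search.best_score_),
        fold_accuracies=fold_acc,
        feature_columns=list(d.X.columns),
        classes=np.unique(d.y),
        seed=seed,
    )


def predict(c: TrainedClassifier, features) -> np.ndarray:
    """Module-level alias for TrainedClassifier.predict."""
    return c.predict(features)
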