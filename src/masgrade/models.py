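"""Classifier configuration, cross-validation, grid search and the cascade.

Five baseline classifiers (Gaussian naive Bayes, decision tree, random
forest, XGBoost, RBF-kernel SVM) are configured with tuned hyperparameters
obtained by grid search + manual refinement on the random-oversampled
training set.  The deployed model is the Logical-SVM-RF cascade:

1. range of motion below 10 deg  ->  MAS "4" (a rigid elbow, pure rule);
2. otherwise the SVM votes; its answer is accepted only for MAS "1"/"3"
   (the grades it separates best);
3. otherwise the random forest decides among MAS "0"/"1+"/"2" (its class
   probabilities are masked to that set and renormalised; ties break toward
   the lower, clinically conservative grade).

Both sub-models are ordinary 5-class classifiers trained on the MAS-4-free
training set; the cascade restricts their roles post hoc.
"""

from __future__ import annotations

import dataclasses
import pickle
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from masgrade.dataset import ScalerParams, apply_scaler, fit_scaler, ros_upsample
from masgrade.features import FEATURE_NAMES
from masgrade.io import MAS_LABELS

SCHEMA_VERSION = 1

FAMILIES = ("gaussian_nb", "decision_tree", "random_forest", "xgboost", "svm")


class XGBLabelClassifier(BaseEstimator, ClassifierMixin):
    """XGBoost with string-label support (internal integer encoding)."""

    def __init__(
        self,
        booster: str = "gbtree",
        gamma: float = 0.1,
        learning_rate: float = 0.1,
        min_child_weight: float = 5,
        n_estimators: int = 100,
        objective: str = "multi:softprob",
        random_state: int = 0,
    ) -> None:
        self.booster = booster
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.min_child_weight = min_child_weight
        self.n_estimators = n_estimators
        self.objective = objective
        self.random_state = random_state

    def fit(self, X, y):
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        self._model = XGBClassifier(
            booster=self.booster,
            gamma=self.gamma,
            learning_rate=self.learning_rate,
            min_child_weight=self.min_child_weight,
            n_estimators=self.n_estimators,
            objective=self.objective,
            random_state=self.random_state,
            num_class=len(self.classes_),
            verbosity=0,
        )
        self._model.fit(np.asarray(X), self._encoder.transform(y))
        return self

    def predict(self, X):
        # with an explicit multi:softprob objective the underlying predict
        # yields per-class probabilities; take the argmax ourselves
        codes = np.argmax(self._model.predict_proba(np.asarray(X)), axis=1)
        return self._encoder.inverse_transform(codes)

    def predict_proba(self, X):
        return self._model.predict_proba(np.asarray(X))


#: Tuned hyperparameters (random-oversampled training set).
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "gaussian_nb": {"var_smoothing": 0.1203},
    "decision_tree": {
        "criterion": "entropy",
        "min_samples_leaf": 3,
        "min_samples_split": 6,
        "splitter": "best",
        "max_features": 8,
    },
    "random_forest": {
        "criterion": "gini",
        "min_samples_leaf": 3,
        "min_samples_split": 6,
        "max_features": 3,
        "n_estimators": 25,
    },
    "xgboost": {
        "booster": "gbtree",
        "gamma": 0.1,
        "learning_rate": 0.1,
        "min_child_weight": 5,
        "n_estimators": 100,
        "objective": "multi:softprob",
    },
    "svm": {"C": 15, "kernel": "rbf", "gamma": "scale"},
}

#: Grid-search ranges for each family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gaussian_nb": {"var_smoothing": np.logspace(-9, 0, 10).tolist()},
    "decision_tree": {
        "criterion": ["gini", "entropy"],
        "min_samples_leaf": list(range(2, 21)),
        "min_samples_split": list(range(2, 21)),
        "splitter": ["best", "random"],
        "max_features": list(range(2, 11)),
    },
    "random_forest": {
        "criterion": ["gini", "entropy"],
        "min_samples_leaf": list(range(2, 21)),
        "min_samples_split": list(range(2, 21)),
        "max_features": list(range(2, 11)),
        "n_estimators": [25, 50, 75, 100],
    },
    "xgboost": {
        "booster": ["gbtree"],
        "gamma": [0.5, 1.5, 2, 5],
        "learning_rate": [0.01, 0.05, 0.1, 0.5],
        "min_child_weight": [5, 10],
        "n_estimators": [50, 100, 200],
    },
    "svm": {
        "kernel": ["linear", "rbf"],
        "gamma": ["scale", "auto"],
        "C": np.logspace(-2, 2, 9).tolist(),
    },
}


@dataclasses.dataclass
class ClassifierSpec:
    """A classifier family plus its hyperparameter assignment."""

    family: str
    hyperparameters: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def default(cls, family: str) -> "ClassifierSpec":
        if family not in FAMILIES:
            raise ValueError(f"unknown classifier family {family!r}")
        return cls(family=family, hyperparameters=dict(DEFAULT_HYPERPARAMETERS[family]))


_CONSTRUCTORS = {
    "gaussian_nb": GaussianNB,
    "decision_tree": DecisionTreeClassifier,
    "random_forest": RandomForestClassifier,
    "xgboost": XGBLabelClassifier,
    "svm": SVC,
}

_SEEDED = {"decision_tree", "random_forest", "xgboost", "svm"}


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate an untrained, fully seeded classifier from a spec.

    Unknown hyperparameter names raise immediately (guards against typos).
    """
    if spec.family not in FAMILIES:
        raise ValueError(f"unknown classifier family {spec.family!r}")
    ctor = _CONSTRUCTORS[spec.family]
    valid = set(ctor().get_params())
    unknown = set(spec.hyperparameters) - valid
    if unknown:
        raise ValueError(
            f"unknown hyperparameter(s) for {spec.family}: {sorted(unknown)}"
        )
    kwargs = dict(spec.hyperparameters)
    if spec.family in _SEEDED:
        kwargs["random_state"] = seed
    return ctor(**kwargs)


def _xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["mas_label"].astype(str).to_numpy()
    return X, y


def crossval_balanced_accuracy(
    spec: ClassifierSpec, train: pd.DataFrame, k: int = 10, seed: int = 0
) -> tuple[float, float]:
    """Stratified k-fold cross-validation scored by balanced accuracy.

    Balanced accuracy is the mean per-class recall; on balanced
    (upsampled) folds it coincides with plain accuracy.  Returns the fold
    mean and standard deviation.
    """
    X, y = _xy(train)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} rows, fewer than "
            f"k={k} folds; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        model = make_classifier(spec, seed=seed)
        model.fit(X[tr], y[tr])
        scores.append(balanced_accuracy_score(y[te], model.predict(X[te])))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std())


def grid_search(
    family: str,
    train: pd.DataFrame,
    param_grid: Mapping[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Exhaustive hyperparameter search with internal cross-validation.

    Scored by balanced accuracy; deterministic given ``seed``.  Returns the
    best spec and the full score table (one row per grid point).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown classifier family {family!r}")
    grid = dict(param_grid) if param_grid is not None else DEFAULT_GRIDS[family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    base = make_classifier(ClassifierSpec(family=family), seed=seed)
    X, y = _xy(train)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(
        clone(base), grid, scoring="balanced_accuracy", cv=cv, refit=False
    )
    search.fit(X, y)
    table = pd.DataFrame(search.cv_results_)
    best = ClassifierSpec(family=family, hyperparameters=dict(search.best_params_))
    return best, table


@dataclasses.dataclass
class CascadeModel:
    """The trained Logical-SVM-RF cascade and its frozen preprocessing."""

    rom_threshold: float
    svm: Any
    rf: Any
    scaler: ScalerParams
    svm_accept_set: tuple[str, ...] = ("1", "3")
    rf_allowed_set: tuple[str, ...] = ("0", "1+", "2")
    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        accept = set(self.svm_accept_set)
        allowed = set(self.rf_allowed_set)
        if accept & allowed:
            raise ValueError("SVM-accept and RF-allowed sets must be disjoint")
        if accept | allowed | {"4"} != set(MAS_LABELS):
            raise ValueError("cascade class sets must cover all six MAS grades")


TRAIN_CLASSES = ("0", "1", "1+", "2", "3")


def train_cascade(
    train: pd.DataFrame,
    seed: int = 0,
    rom_threshold: float = 10.0,
    svm_spec: ClassifierSpec | None = None,
    rf_spec: ClassifierSpec | None = None,
) -> CascadeModel:
    """Fit the cascade: scaler, random oversampling, then SVM and RF.

    The training set must contain exactly the five classifiable grades
    (MAS 4 is excluded upstream and handled by the ROM rule).
    """
    present = set(train["mas_label"].astype(str))
    if "4" in present:
        raise ValueError("MAS 4 rows must be excluded before cascade training")
    missing = sorted(set(TRAIN_CLASSES) - present)
    if missing:
        raise ValueError(f"training set is missing MAS grade(s): {missing}")
    scaler = fit_scaler(train)
    scaled = apply_scaler(scaler, train)
    balanced = ros_upsample(scaled, seed=seed)
    X, y = _xy(balanced)
    svm = make_classifier(svm_spec or ClassifierSpec.default("svm"), seed=seed)
    rf = make_classifier(rf_spec or ClassifierSpec.default("random_forest"), seed=seed)
    svm.fit(X, y)
    rf.fit(X, y)
    return CascadeModel(
        rom_threshold=rom_threshold, svm=svm, rf=rf, scaler=scaler, seed=seed
    )


def _scale_row(model: CascadeModel, features: Mapping[str, float]) -> np.ndarray:
    vals = []
    for name in model.feature_names:
        v = float(features[name])
        if not np.isfinite(v):
            raise ValueError(f"feature {name!r} is not finite: {v}")
        vals.append((v - model.scaler.mean[name]) / model.scaler.std[name])
    return np.asarray(vals)[None, :]


def predict_cascade(
    model: CascadeModel, features: Mapping[str, float], rom: float
) -> str:
    """Predict one MAS grade from raw (unscaled) features and the segment ROM.

    ``rom`` is in degrees.  Strictly below the threshold means MAS "4";
    at or above it the classifiers decide.
    """
    if rom < model.rom_threshold:
        return "4"
    X = _scale_row(model, features)
    svm_label = str(model.svm.predict(X)[0])
    if svm_label in model.svm_accept_set:
        return svm_label
    proba = model.rf.predict_proba(X)[0]
    classes = [str(c) for c in model.rf.classes_]
    allowed = [c for c in model.rf_allowed_set]  # MAS order: ties -> lower grade
    masked = np.array([proba[classes.index(c)] for c in allowed])
    return allowed[int(np.argmax(masked))]


def predict_cascade_frame(model: CascadeModel, table: pd.DataFrame) -> pd.Series:
    """Vector version of :func:`predict_cascade` over a feature table.

    The ROM rule reads the raw ``rom`` column (degrees, pre-scaling).
    """
    labels = [
        predict_cascade(model, row[list(FEATURE_NAMES)].to_dict(), rom=row["rom"])
        for _, row in table.iterrows()
    ]
    return pd.Series(labels, index=table.index, name="predicted_mas")


def save_cascade(model: CascadeModel, path: str | Path) -> None:
    """Serialise the trained cascade (scaler, sub-models, metadata) to one file."""
    with open(path, "wb") as fh:
        pickle.dump({"schema_version": SCHEMA_VERSION, "model": model}, fh)


def load_cascade(path: str | Path) -> CascadeModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"cascade schema version {payload.get('schema_version')} does not "
            f"match expected {SCHEMA_VERSION}"
        )
    model = payload["model"]
    if tuple(model.feature_names) != FEATURE_NAMES:
        raise ValueError("cascade feature schema does not match this package version")
    return model
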