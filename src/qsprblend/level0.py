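"""The four tree-ensemble base learners behind a uniform contract.

The level-0 pool consists of two bagging ensembles — random forests of
full-grown trees and extremely randomized trees — and two boosting
ensembles — adaptive boosting (AdaBoost) and gradient boosting machines
(GBM). They are consumed from scikit-learn; this module owns the contract:
spec validation, deterministic fitting, name-aligned prediction, extraction
of the normalized mean-decrease-in-impurity importance vector, and
randomized hyperparameter search by k-fold cross-validation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold, ParameterSampler, StratifiedKFold, cross_val_score

from .dataset import DescriptorTable
from .importance import ImportanceProfile

__all__ = [
    "KINDS",
    "Level0Spec",
    "FittedLevel0",
    "fit_level0",
    "predict_level0",
    "tune_level0",
    "default_search_space",
    "save_model",
    "load_model",
]

KINDS = (
    "bagged_full_trees",
    "extremely_randomized_trees",
    "adaptive_boosting",
    "gradient_boosting",
)

# common shorthand accepted everywhere a kind is named
_ALIASES = {
    "rf": "bagged_full_trees",
    "random_forest": "bagged_full_trees",
    "extratrees": "extremely_randomized_trees",
    "et": "extremely_randomized_trees",
    "adaboost": "adaptive_boosting",
    "ada": "adaptive_boosting",
    "gbm": "gradient_boosting",
    "gb": "gradient_boosting",
}

_ESTIMATORS = {
    ("bagged_full_trees", "regression"): RandomForestRegressor,
    ("bagged_full_trees", "classification"): RandomForestClassifier,
    ("extremely_randomized_trees", "regression"): ExtraTreesRegressor,
    ("extremely_randomized_trees", "classification"): ExtraTreesClassifier,
    ("adaptive_boosting", "regression"): AdaBoostRegressor,
    ("adaptive_boosting", "classification"): AdaBoostClassifier,
    ("gradient_boosting", "regression"): GradientBoostingRegressor,
    ("gradient_boosting", "classification"): GradientBoostingClassifier,
}

_BOOSTERS = ("adaptive_boosting", "gradient_boosting")


def canonical_kind(kind: str) -> str:
    kind = _ALIASES.get(kind.lower(), kind.lower())
    if kind not in KINDS:
        raise ValueError(f"unknown level-0 kind {kind!r}; choose one of {KINDS}")
    return kind


def default_search_space(kind: str) -> dict[str, list]:
    """Config-overridable search grid for :func:`tune_level0`."""
    kind = canonical_kind(kind)
    space: dict[str, list] = {
        "n_estimators": [50, 100, 200, 500],
        "max_depth": [3, 5, 8, None],
    }
    if kind in _BOOSTERS:
        space["learning_rate"] = [0.01, 0.05, 0.1, 0.2]
    if kind == "adaptive_boosting":
        # AdaBoost takes depth via its base tree, not a max_depth kwarg
        space.pop("max_depth")
    return space


@dataclass
class Level0Spec:
    """One base learner: kind, hyperparameters, seed and task."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    random_state: int = 0
    task: str = "regression"

    def __post_init__(self) -> None:
        self.kind = canonical_kind(self.kind)
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        # fail early on hyperparameters the backing estimator cannot take
        probe = _ESTIMATORS[(self.kind, self.task)]()
        valid = set(probe.get_params())
        unknown = set(self.hyperparameters) - valid - {"max_depth"}
        if unknown:
            raise ValueError(
                f"invalid hyperparameters for {self.kind}: {sorted(unknown)}"
            )

    def build(self):
        """Instantiate the (unfitted) scikit-learn estimator."""
        cls = _ESTIMATORS[(self.kind, self.task)]
        params = dict(self.hyperparameters)
        if self.kind == "adaptive_boosting" and "max_depth" in params:
            from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

            depth = params.pop("max_depth")
            tree = (
                DecisionTreeRegressor(max_depth=depth)
                if self.task == "regression"
                else DecisionTreeClassifier(max_depth=depth)
            )
            params["estimator"] = tree
        return cls(random_state=self.random_state, **params)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "hyperparameters": copy.deepcopy(self.hyperparameters),
            "random_state": self.random_state,
            "task": self.task,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Level0Spec":
        return cls(**payload)


@dataclass
class FittedLevel0:
    """A fitted base learner plus its normalized importance profile."""

    spec: Level0Spec
    learner: object
    importance: ImportanceProfile
    feature_names: list[str]
    classes_: np.ndarray | None = None
    positive_label: object = None


def _normalized_importance(raw: np.ndarray) -> np.ndarray:
    raw = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = raw.sum()
    if total <= 0:
        return np.full(raw.size, 1.0 / raw.size)
    return raw / total


def fit_level0(train: DescriptorTable, spec: Level0Spec) -> FittedLevel0:
    """Fit one base learner; deterministic given (data, spec, random_state)."""
    if spec.task != train.task:
        raise ValueError(f"spec task {spec.task!r} != table task {train.task!r}")
    if train.task == "classification" and len(np.unique(train.y)) < 2:
        raise ValueError("classification target has a single class")
    learner = spec.build()
    learner.fit(train.X, train.y)
    importance = ImportanceProfile(
        feature_names=list(train.feature_names),
        scores=_normalized_importance(learner.feature_importances_),
        source=spec.kind,
    )
    return FittedLevel0(
        spec=spec,
        learner=learner,
        importance=importance,
        feature_names=list(train.feature_names),
        classes_=getattr(learner, "classes_", None),
        positive_label=train.positive_label if train.task == "classification" else None,
    )


def _aligned_X(model: FittedLevel0, table: DescriptorTable) -> np.ndarray:
    if list(table.feature_names) == model.feature_names:
        return table.X
    trained, given = set(model.feature_names), set(table.feature_names)
    if trained != given:
        missing = sorted(trained - given)
        extra = sorted(given - trained)
        raise ValueError(
            f"feature mismatch: missing from table {missing}, unexpected {extra}"
        )
    order = [table.feature_names.index(name) for name in model.feature_names]
    return table.X[:, order]


def predict_level0(
    model: FittedLevel0, table: DescriptorTable, return_proba: bool = False
) -> np.ndarray:
    """Predict on a table whose features match training features by name.

    Regression returns the continuous prediction. Classification returns
    hard labels, or the positive-class probability when ``return_proba``.
    """
    if table.n_samples == 0:
        return np.empty(0)
    X = _aligned_X(model, table)
    if model.spec.task == "regression":
        return np.asarray(model.learner.predict(X), dtype=float)
    if return_proba:
        proba = model.learner.predict_proba(X)
        pos_col = int(np.flatnonzero(model.classes_ == model.positive_label)[0])
        return np.asarray(proba[:, pos_col], dtype=float)
    return np.asarray(model.learner.predict(X))


def tune_level0(
    train: DescriptorTable,
    spec: Level0Spec,
    search_space: dict[str, list] | None = None,
    n_iter: int = 20,
    k: int = 5,
    seed: int = 0,
) -> Level0Spec:
    """Randomized hyperparameter search with k-fold cross-validation.

    Candidates are drawn from ``search_space`` in a seeded order and scored
    by mean CV RMSE (regression, lower is better) or mean CV accuracy
    (classification, higher is better; folds class-stratified). Ties keep
    the earlier-sampled candidate. Returns a new spec with the winning
    hyperparameters merged in.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if k < 2:
        raise ValueError("k must be at least 2")
    if search_space is None:
        search_space = default_search_space(spec.kind)
    if not search_space:
        raise ValueError("search_space must be nonempty")

    n_grid = int(np.prod([len(v) for v in search_space.values()]))
    sampler = ParameterSampler(
        search_space, n_iter=min(n_iter, n_grid), random_state=seed
    )
    if spec.task == "regression":
        cv = KFold(n_splits=k, shuffle=True, random_state=seed)
        scoring = "neg_root_mean_squared_error"
    else:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scoring = "accuracy"

    best_params, best_score = None, -np.inf
    for params in sampler:
        candidate = Level0Spec(
            kind=spec.kind,
            hyperparameters={**spec.hyperparameters, **params},
            random_state=spec.random_state,
            task=spec.task,
        )
        scores = cross_val_score(
            candidate.build(), train.X, train.y, cv=cv, scoring=scoring
        )
        mean = float(np.mean(scores))
        if mean > best_score:  # strict: ties keep the earlier candidate
            best_score, best_params = mean, candidate.hyperparameters
    return Level0Spec(
        kind=spec.kind,
        hyperparameters=best_params,
        random_state=spec.random_state,
        task=spec.task,
    )


def save_model(model: FittedLevel0, path) -> None:
    """Persist via joblib with a format version tag."""
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> FittedLevel0:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognized model file format")
    return payload["model"]
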