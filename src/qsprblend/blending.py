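"""Level-0 / level-1 blending of tree-ensemble QSPR models.

Blending is a simplified stacked generalization: a pool of n base learners
(level-0, here the four tree ensembles) each produce a prediction, and a
single combiner (level-1, the "blender") maps the n-column prediction
matrix to the final output. Three combiner variants are supported:

* uniform — no meta-learning: the arithmetic mean of predictions in
  regression, majority vote of hard labels in classification. Weights are
  exactly 1/n.
* linear — multiple linear regression (regression) or logistic regression
  (classification) on the level-0 predictions; weights are the normalized
  absolute coefficients.
* any — a small gradient-boosting model as a non-linear combiner
  (10 estimators; depth 8 / learning rate 0.1 for regression, depth 4 for
  classification); weights are its impurity feature importances.

The weight vector w lives on the probability simplex and also drives the
aggregated feature-importance profile FI_blend = sum_i w_i FI_i, which is
what makes the blend interpretable rather than a black box.

Usage follows the Model/Results convention::

    model = BlendingModel(train_table, specs, variant="any")
    result = model.fit(seed=0)          # -> Blender
    yhat = result.predict(test_table)
    print(result.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.model_selection import train_test_split

from . import level0 as _l0
from .dataset import DescriptorTable
from .importance import ImportanceProfile, blend_importance
from .metrics import MetricReport, classification_metrics, confusion_table, regression_metrics

__all__ = [
    "VARIANTS",
    "BlendConfig",
    "BlendingModel",
    "Blender",
    "fit_blend",
    "fit_blend_config",
    "predict_blend",
    "extract_weights",
]

VARIANTS = ("uniform", "linear", "any")

# level-1 GBM defaults for the "any" variant, per task
_ANY_DEFAULTS = {
    "regression": {"n_estimators": 10, "max_depth": 8, "learning_rate": 0.1},
    "classification": {"n_estimators": 10, "max_depth": 4},
}


def default_specs(task: str, random_state: int = 0) -> list[_l0.Level0Spec]:
    """The canonical four-model level-0 pool."""
    return [
        _l0.Level0Spec(kind=kind, random_state=random_state, task=task)
        for kind in _l0.KINDS
    ]


@dataclass
class BlendConfig:
    """Declarative description of a blend, reusable across seeds."""

    specs: list
    variant: str = "uniform"
    blend_mode: str = "holdout"
    holdout_fraction: float = 0.2
    level1_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.blend_mode not in ("insample", "holdout"):
            raise ValueError(f"unknown blend_mode {self.blend_mode!r}")
        if len(self.specs) < 2:
            raise ValueError("blending needs at least two level-0 models")
        if self.blend_mode == "holdout" and not 0.0 < self.holdout_fraction <= 0.5:
            raise ValueError("holdout_fraction must lie in (0, 0.5]")


class BlendingModel:
    """Unfitted blend: training table + level-0 specs + combiner choice.

    ``fit(seed)`` returns a :class:`Blender` results object. The default
    blend mode is holdout (fraction 0.2): the level-1 combiner is trained on
    level-0 predictions for samples those models never saw, which avoids the
    information leak of feeding training-set predictions straight through;
    ``blend_mode="insample"`` reproduces the straight-through flow (and its
    near-perfect training fits).
    """

    def __init__(
        self,
        train: DescriptorTable,
        specs=None,
        variant: str = "uniform",
        blend_mode: str = "holdout",
        holdout_fraction: float = 0.2,
        level1_params: dict | None = None,
    ):
        self.train = train
        if specs is None:
            specs = default_specs(train.task)
        for spec in specs:
            if spec.task != train.task:
                raise ValueError(
                    f"level-0 spec task {spec.task!r} != table task {train.task!r}"
                )
        self.config = BlendConfig(
            specs=list(specs),
            variant=variant,
            blend_mode=blend_mode,
            holdout_fraction=holdout_fraction,
            level1_params=dict(level1_params or {}),
        )

    @classmethod
    def from_dataframe(
        cls, df, target_column: str, task: str = "regression", **kwargs
    ) -> "BlendingModel":
        """Build from a pandas DataFrame whose first column is the sample id."""
        from . import dataset as _ds

        id_col = df.columns[0]
        feature_cols = [c for c in df.columns if c not in (id_col, target_column)]
        table = DescriptorTable(
            sample_ids=df[id_col].tolist(),
            feature_names=feature_cols,
            X=df[feature_cols].to_numpy(dtype=float),
            y=df[target_column].to_numpy(),
            task=task,
        )
        return cls(table, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "Blender":
        cfg = self.config
        train = self.train
        task = train.task

        if cfg.blend_mode == "holdout" and cfg.variant != "uniform":
            idx = np.arange(train.n_samples)
            strat = train.y if task == "classification" else None
            fit_idx, hold_idx = train_test_split(
                idx,
                test_size=cfg.holdout_fraction,
                random_state=_small_seed(seed),
                stratify=strat,
            )
            fit_part, hold_part = train.subset(fit_idx), train.subset(hold_idx)
            stage1 = [_l0.fit_level0(fit_part, spec) for spec in cfg.specs]
            meta_X = _meta_matrix(stage1, hold_part)
            meta_y = hold_part.y
        else:
            stage1 = None
            meta_X = meta_y = None

        fitted = [_l0.fit_level0(train, spec) for spec in cfg.specs]
        if cfg.variant != "uniform" and meta_X is None:
            meta_X = _meta_matrix(fitted, train)
            meta_y = train.y

        level1 = None
        fallback = False
        if cfg.variant != "uniform":
            level1, fallback = _fit_level1(
                cfg, task, meta_X, meta_y, seed,
                positive_label=train.positive_label,
            )

        blender = Blender(
            variant="uniform" if fallback else cfg.variant,
            requested_variant=cfg.variant,
            level0=fitted,
            level1=None if fallback else level1,
            blend_mode=cfg.blend_mode,
            holdout_fraction=cfg.holdout_fraction,
            task=task,
            positive_label=train.positive_label,
            negative_label=_negative_label(train),
            seed=seed,
            fallback=fallback,
        )
        blender.weights = extract_weights(blender)
        blender.importance = blend_importance(
            [m.importance for m in fitted], blender.weights
        )
        blender.importance.source = f"{blender.variant}_blend"
        return blender


def _small_seed(seed: int) -> int:
    return int(seed) % (2**31 - 1)


def _meta_matrix(models, table: DescriptorTable) -> np.ndarray:
    """n_samples x n_models level-0 prediction matrix (probabilities for
    classification: graded inputs are what linear/GBM combiners need)."""
    cols = []
    for m in models:
        if m.spec.task == "regression":
            cols.append(_l0.predict_level0(m, table))
        else:
            cols.append(_l0.predict_level0(m, table, return_proba=True))
    return np.column_stack(cols)


def _fit_level1(cfg: BlendConfig, task, meta_X, meta_y, seed, positive_label):
    """Fit the combiner; returns (model, fallback_to_uniform)."""
    if cfg.variant == "linear":
        if task == "regression":
            model = LinearRegression()
        else:
            model = LogisticRegression(max_iter=1000)
        target = meta_y if task == "regression" else (meta_y == positive_label).astype(int)
    else:
        params = {**_ANY_DEFAULTS[task], **cfg.level1_params}
        if task == "regression":
            model = GradientBoostingRegressor(random_state=_small_seed(seed), **params)
        else:
            model = GradientBoostingClassifier(random_state=_small_seed(seed), **params)
        target = meta_y if task == "regression" else (meta_y == positive_label).astype(int)

    if task == "classification" and len(np.unique(target)) < 2:
        warnings.warn("level-1 training labels are single-class; using uniform weights")
        return None, True
    model.fit(meta_X, target)

    fitted_pred = model.predict(meta_X)
    if np.ptp(np.asarray(fitted_pred, dtype=float)) == 0 and np.ptp(
        np.asarray(target, dtype=float)
    ) > 0:
        warnings.warn("degenerate level-1 fit (constant predictions); using uniform weights")
        return None, True
    if cfg.variant == "linear":
        coefs = model.coef_.ravel()
        if np.all(np.abs(coefs) == 0):
            warnings.warn("all level-1 coefficients are zero; using uniform weights")
            return None, True
    return model, False


@dataclass
class Blender:
    """Fitted blend results: level-0 pool, combiner, weights, importances.

    Produced by :meth:`BlendingModel.fit`; carries ``predict``, ``evaluate``
    and ``summary``. ``fallback`` is True when a degenerate level-1 fit was
    replaced by the uniform rule.
    """

    variant: str
    level0: list
    level1: object | None
    blend_mode: str
    holdout_fraction: float
    task: str
    positive_label: object = 1
    negative_label: object = 0
    seed: int = 0
    requested_variant: str | None = None
    fallback: bool = False
    weights: np.ndarray | None = None
    importance: ImportanceProfile | None = None

    @property
    def n_models(self) -> int:
        return len(self.level0)

    @property
    def model_kinds(self) -> list[str]:
        return [m.spec.kind for m in self.level0]

    # -- prediction --------------------------------------------------------

    def predict(self, table: DescriptorTable) -> np.ndarray:
        return predict_blend(self, table)

    def predict_proba(self, table: DescriptorTable) -> np.ndarray:
        """Positive-class probability of the blend (classification only)."""
        if self.task != "classification":
            raise ValueError("predict_proba is classification-only")
        if table.n_samples == 0:
            return np.empty(0)
        meta = _meta_matrix(self.level0, table)
        if self.variant == "uniform":
            return meta.mean(axis=1)
        pos_col = int(np.flatnonzero(self.level1.classes_ == 1)[0])
        return self.level1.predict_proba(meta)[:, pos_col]

    def evaluate(self, table: DescriptorTable) -> MetricReport:
        """Score the blend on a table (train or held-out test)."""
        pred = self.predict(table)
        if self.task == "regression":
            return regression_metrics(table.y, pred)
        ct = confusion_table(table.y, pred, self.positive_label)
        return classification_metrics(ct)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"{self.variant} blending ({self.task}), "
            f"mode={self.blend_mode}"
            + (f", holdout={self.holdout_fraction}" if self.blend_mode == "holdout" else ""),
            f"{'level-0 model':<30}{'weight':>10}",
        ]
        for kind, w in zip(self.model_kinds, self.weights):
            lines.append(f"{kind:<30}{w:>10.4f}")
        if self.fallback:
            lines.append("note: degenerate level-1 fit; fell back to uniform weights")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Persist as a directory: config JSON, level-0 models, level-1, weights."""
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {
            "variant": self.variant,
            "requested_variant": self.requested_variant,
            "blend_mode": self.blend_mode,
            "holdout_fraction": self.holdout_fraction,
            "task": self.task,
            "seed": self.seed,
            "model_kinds": self.model_kinds,
            "fallback": self.fallback,
        }
        (directory / "config.json").write_text(json.dumps(config, indent=2))
        (directory / "weights.json").write_text(
            json.dumps({k: float(w) for k, w in zip(self.model_kinds, self.weights)},
                       indent=2)
        )
        for i, m in enumerate(self.level0):
            _l0.save_model(m, directory / f"level0_{i}_{m.spec.kind}.joblib")
        if self.level1 is not None:
            joblib.dump(self.level1, directory / "level1.joblib")


# -- functional surface ----------------------------------------------------

def fit_blend(
    train: DescriptorTable,
    specs=None,
    variant: str = "uniform",
    blend_mode: str = "holdout",
    holdout_fraction: float = 0.2,
    seed: int = 0,
    level1_params: dict | None = None,
) -> Blender:
    """Fit a blend in one call; see :class:`BlendingModel`."""
    return BlendingModel(
        train,
        specs=specs,
        variant=variant,
        blend_mode=blend_mode,
        holdout_fraction=holdout_fraction,
        level1_params=level1_params,
    ).fit(seed=seed)


def fit_blend_config(train: DescriptorTable, cfg: BlendConfig, seed: int = 0) -> Blender:
    """Fit a :class:`BlendConfig`, re-seeding every level-0 model with ``seed``.

    This is the repetition protocol used for importance stability: the same
    configuration refit under random states 0, 1, 2, ...
    """
    specs = [
        _l0.Level0Spec(
            kind=s.kind,
            hyperparameters=dict(s.hyperparameters),
            random_state=_small_seed(seed),
            task=s.task,
        )
        for s in cfg.specs
    ]
    return BlendingModel(
        train,
        specs=specs,
        variant=cfg.variant,
        blend_mode=cfg.blend_mode,
        holdout_fraction=cfg.holdout_fraction,
        level1_params=cfg.level1_params,
    ).fit(seed=seed)


def predict_blend(blender: Blender, table: DescriptorTable) -> np.ndarray:
    """Final blended prediction.

    uniform regression: arithmetic mean of level-0 predictions.
    uniform classification: majority vote of hard labels; even-vote ties go
    positive when the mean positive-class probability is >= 0.5.
    linear / any: level-1 applied to the level-0 prediction matrix
    (positive-class probabilities for classification).
    """
    if table.n_samples == 0:
        return np.empty(0)
    if blender.variant == "uniform":
        if blender.task == "regression":
            preds = np.column_stack(
                [_l0.predict_level0(m, table) for m in blender.level0]
            )
            return preds.mean(axis=1)
        votes = np.column_stack(
            [
                (_l0.predict_level0(m, table) == blender.positive_label)
                for m in blender.level0
            ]
        )
        pos_votes = votes.sum(axis=1)
        n = blender.n_models
        decided_pos = pos_votes * 2 > n
        tied = pos_votes * 2 == n
        if tied.any():
            mean_proba = _meta_matrix(blender.level0, table).mean(axis=1)
            decided_pos = decided_pos | (tied & (mean_proba >= 0.5))
        return _labels_from_mask(decided_pos, table, blender)

    meta = _meta_matrix(blender.level0, table)
    if blender.task == "regression":
        return np.asarray(blender.level1.predict(meta), dtype=float)
    return _labels_from_mask(blender.level1.predict(meta).astype(bool), table, blender)


def _negative_label(train: DescriptorTable):
    if train.task != "classification":
        return 0
    negatives = [l for l in np.unique(train.y) if l != train.positive_label]
    return negatives[0] if negatives else 0


def _labels_from_mask(is_pos: np.ndarray, table: DescriptorTable, blender: Blender):
    return np.where(is_pos, blender.positive_label, blender.negative_label)


def extract_weights(blender: Blender) -> np.ndarray:
    """The simplex weight vector w of a fitted blend.

    uniform -> (1/n, ..., 1/n); linear -> normalized absolute level-1
    coefficients (intercept excluded); any -> the level-1 GBM's impurity
    importances over its n inputs.
    """
    n = blender.n_models
    if blender.variant == "uniform" or blender.level1 is None:
        return np.full(n, 1.0 / n)
    if blender.variant == "linear":
        coefs = np.abs(np.asarray(blender.level1.coef_).ravel())
        total = coefs.sum()
        if total == 0:
            warnings.warn("all-zero linear coefficients; uniform weights")
            return np.full(n, 1.0 / n)
        return coefs / total
    raw = np.asarray(blender.level1.feature_importances_, dtype=float)
    total = raw.sum()
    if total <= 0:
        warnings.warn("level-1 importances are all zero; uniform weights")
        return np.full(n, 1.0 / n)
    return raw / total
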