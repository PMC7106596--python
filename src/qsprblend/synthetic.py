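"""Synthetic descriptor tables with known ground truth.

Real QSPR descriptor matrices are wide (hundreds to thousands of columns)
with only a small informative subset driving the property. The generator
emulates that shape: independent standard-normal features, a planted linear
signal over ``n_informative`` of them (optionally plus one pairwise
interaction), additive Gaussian noise for regression, and quantile-threshold
labels for classification so the class balance is controlled exactly —
default prevalence 0.73 mimics the 2780/3786 liquid-crystal imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import DescriptorTable

__all__ = ["SyntheticSpec", "generate_regression", "generate_classification"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    effect_sizes are the linear coefficients of the informative features
    (default: all 1.0). nonlinearity="interactions" adds the product of the
    first two informative features to the latent score, giving tree
    ensembles a term a linear model cannot represent. noise_sd is the
    standard deviation of the additive Gaussian noise on the regression
    target (features are standard-normal, so noise_sd=0.5 against unit
    effects is moderate noise).
    """

    n_samples: int = 400
    n_features: int = 100
    n_informative: int = 5
    effect_sizes: list[float] | None = None
    nonlinearity: str = "interactions"
    noise_sd: float = 0.5
    positive_fraction: float = 0.73
    seed: int = 0
    positive_label: object = field(default=1)
    negative_label: object = field(default=0)

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_informative < 0 or self.n_features < 1 or self.n_samples < 1:
            raise ValueError("sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie strictly in (0, 1)")
        if self.nonlinearity not in ("none", "interactions"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.effect_sizes is None:
            self.effect_sizes = [1.0] * self.n_informative
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError("effect_sizes must have length n_informative")


def _latent(spec: SyntheticSpec, rng: np.random.Generator):
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = np.arange(spec.n_informative)
    score = X[:, informative] @ np.asarray(spec.effect_sizes, dtype=float)
    if spec.nonlinearity == "interactions" and spec.n_informative >= 2:
        score = score + X[:, informative[0]] * X[:, informative[1]]
    noise = spec.noise_sd * rng.standard_normal(spec.n_samples)
    return X, score + noise, informative


def _feature_names(p: int) -> list[str]:
    width = len(str(p - 1))
    return [f"desc_{i:0{width}d}" for i in range(p)]


def generate_regression(spec: SyntheticSpec) -> tuple[DescriptorTable, np.ndarray]:
    """Regression table plus the informative column indices."""
    rng = np.random.default_rng(spec.seed)
    X, y, informative = _latent(spec, rng)
    table = DescriptorTable(
        sample_ids=[f"s{i}" for i in range(spec.n_samples)],
        feature_names=_feature_names(spec.n_features),
        X=X,
        y=y,
        task="regression",
    )
    return table, informative


def generate_classification(spec: SyntheticSpec) -> tuple[DescriptorTable, np.ndarray]:
    """Binary table with exact class prevalence, plus informative indices.

    Labels are positive for the top ``positive_fraction`` quantile of the
    noisy latent score (ties broken by score order), so the positive count
    is exactly round(positive_fraction * n).
    """
    rng = np.random.default_rng(spec.seed)
    X, score, informative = _latent(spec, rng)
    n_pos = int(round(spec.positive_fraction * spec.n_samples))
    n_pos = min(max(n_pos, 1), spec.n_samples - 1)
    order = np.argsort(score, kind="stable")
    is_pos = np.zeros(spec.n_samples, dtype=bool)
    is_pos[order[-n_pos:]] = True
    y = np.where(is_pos, spec.positive_label, spec.negative_label)
    table = DescriptorTable(
        sample_ids=[f"s{i}" for i in range(spec.n_samples)],
        feature_names=_feature_names(spec.n_features),
        X=X,
        y=np.asarray(y),
        task="classification",
        positive_label=spec.positive_label,
    )
    return table, informative


def write_ground_truth(spec: SyntheticSpec, informative: np.ndarray, path) -> None:
    """Sidecar JSON naming the planted features and generator settings."""
    payload = {
        "informative_indices": [int(i) for i in informative],
        "informative_names": [_feature_names(spec.n_features)[i] for i in informative],
        "effect_sizes": list(map(float, spec.effect_sizes)),
        "nonlinearity": spec.nonlinearity,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
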