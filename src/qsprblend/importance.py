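"""Feature-importance profiles, weighted aggregation and ranking.

Every tree ensemble here exposes a mean-decrease-in-impurity importance
vector, normalized to the probability simplex. A blend of n base models with
weight vector w aggregates them as

    FI_blend = sum_i w_i * FI_i

which stays on the simplex whenever the inputs and weights do. Because the
impurity importances depend on the ensemble's random state, profiles are
conventionally averaged over repeated fits with different seeds before
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceProfile",
    "blend_importance",
    "repeated_importance",
    "rank_features",
    "export_ranking_tsv",
    "plot_ranking",
]

_TOL = 1e-9


@dataclass
class ImportanceProfile:
    """Per-feature nonnegative scores summing to 1.

    ``source`` tags provenance (a learner kind or blend variant);
    ``n_repeats`` counts the random states averaged into the profile.
    """

    feature_names: list[str]
    scores: np.ndarray
    source: str = ""
    n_repeats: int = 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_names) != self.scores.size:
            raise ValueError("feature_names and scores must agree in length")
        if (self.scores < -_TOL).any():
            raise ValueError("importance scores must be nonnegative")
        self.scores = np.clip(self.scores, 0.0, None)
        total = self.scores.sum()
        if abs(total - 1.0) > _TOL:
            if total <= 0:
                raise ValueError("importance scores must not all be zero")
            self.scores = self.scores / total

    @property
    def n_features(self) -> int:
        return self.scores.size

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.feature_names, name=self.source)


def blend_importance(
    profiles: list[ImportanceProfile], weights
) -> ImportanceProfile:
    """Weighted sum of importance profiles: FI_blend = sum_i w_i FI_i."""
    if not profiles:
        raise ValueError("need at least one profile")
    w = np.asarray(weights, dtype=float)
    if w.size != len(profiles):
        raise ValueError("weights must match the number of profiles")
    if (w < -_TOL).any() or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must lie on the probability simplex")
    names = profiles[0].feature_names
    for p in profiles[1:]:
        if p.feature_names != names:
            raise ValueError("profiles disagree on feature names")
    blended = np.zeros(len(names))
    for wi, p in zip(w, profiles):
        blended += wi * p.scores
    return ImportanceProfile(
        feature_names=list(names),
        scores=blended,
        source="blend",
        n_repeats=max(p.n_repeats for p in profiles),
    )


def repeated_importance(train, spec_or_blendcfg, seeds=None) -> ImportanceProfile:
    """Average importance over refits with different random states.

    ``spec_or_blendcfg`` is a :class:`~qsprblend.level0.Level0Spec` or a
    :class:`~qsprblend.blending.BlendConfig`; the model is refit once per
    seed and the importance vectors averaged elementwise. Default seeds are
    0-9 (ten repetitions, the field's usual stability protocol).
    """
    from . import blending, level0  # local import: avoids a module cycle

    if seeds is None:
        seeds = list(range(10))
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seeds must be nonempty")

    vectors = []
    names = None
    source = ""
    for seed in seeds:
        try:
            if isinstance(spec_or_blendcfg, level0.Level0Spec):
                spec = level0.Level0Spec(
                    kind=spec_or_blendcfg.kind,
                    hyperparameters=dict(spec_or_blendcfg.hyperparameters),
                    random_state=seed,
                    task=spec_or_blendcfg.task,
                )
                profile = level0.fit_level0(train, spec).importance
            elif isinstance(spec_or_blendcfg, blending.BlendConfig):
                profile = blending.fit_blend_config(
                    train, spec_or_blendcfg, seed=seed
                ).importance
            else:
                raise TypeError(
                    "expected a Level0Spec or BlendConfig, got "
                    f"{type(spec_or_blendcfg).__name__}"
                )
        except TypeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"fit failed for random state {seed}: {exc}") from exc
        vectors.append(profile.scores)
        names = profile.feature_names
        source = profile.source
    return ImportanceProfile(
        feature_names=list(names),
        scores=np.mean(vectors, axis=0),
        source=source,
        n_repeats=len(seeds),
    )


def rank_features(profile: ImportanceProfile, top_k: int | None = None):
    """Descending ranking as (name, score) pairs.

    Ties break by ascending feature name so rankings are deterministic.
    """
    n = profile.n_features
    if top_k is None:
        top_k = n
    if not 1 <= top_k <= n:
        raise ValueError(f"top_k must lie in [1, {n}], got {top_k}")
    order = sorted(
        range(n), key=lambda i: (-profile.scores[i], profile.feature_names[i])
    )
    return [(profile.feature_names[i], float(profile.scores[i])) for i in order[:top_k]]


def export_ranking_tsv(profile: ImportanceProfile, path, top_k: int | None = None) -> None:
    """TSV export: rank, feature, score, source, n_repeats."""
    ranking = rank_features(profile, top_k)
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking) + 1),
            "feature": [name for name, _ in ranking],
            "score": [score for _, score in ranking],
            "source": profile.source,
            "n_repeats": profile.n_repeats,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def plot_ranking(profile: ImportanceProfile, top_k: int = 10, ax=None, path=None):
    """Horizontal bar chart of the top-k features, largest at the top."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranking = rank_features(profile, min(top_k, profile.n_features))
    names = [name for name, _ in ranking][::-1]
    scores = [score for _, score in ranking][::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1))
    ax.barh(names, scores, color="#4878a8")
    ax.set_xlabel("feature importance")
    title = profile.source or "importance"
    ax.set_title(f"top {len(names)} features ({title})")
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
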