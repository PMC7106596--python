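"""Descriptor tables and train/test splitting.

A :class:`DescriptorTable` is the package's in-memory container for a QSPR
dataset: one row per sample, numeric molecular-descriptor columns, a
continuous or binary target, and an optional per-sample group label (for
example the chromophore family of a dye) used for grouped stratification.

Tables are read from and written to plain delimited text (CSV/TSV, header
row, first column = sample id), the format descriptor-generation tools emit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorTable",
    "read_table",
    "write_table",
    "split_train_test",
    "write_split_manifest",
]


@dataclass
class DescriptorTable:
    """Samples x descriptors matrix with target and optional group labels.

    ``task`` is ``"regression"`` (continuous y) or ``"classification"``
    (binary y, with ``positive_label`` the class treated as positive).
    ``code_maps`` records integer encodings applied to declared categorical
    descriptor columns (e.g. the solvent species).
    """

    sample_ids: list
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    task: str
    group: np.ndarray | None = None
    positive_label: object = 1
    code_maps: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = self.X.shape[0]
        if len(self.sample_ids) != n or len(self.y) != n:
            raise ValueError("sample_ids, X and y must agree in length")
        if len(set(map(str, self.sample_ids))) != n:
            raise ValueError("sample ids must be unique")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names must match the number of columns of X")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if self.task == "classification":
            classes = np.unique(self.y)
            if len(classes) != 2 and n > 0:
                raise ValueError(
                    f"classification target must be binary, found {len(classes)} classes"
                )
        else:
            self.y = self.y.astype(float)
            if np.isnan(self.y).any():
                raise ValueError("y contains missing values")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != n:
                raise ValueError("group labels must match the number of samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, indices) -> "DescriptorTable":
        """New table restricted to the given row indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return DescriptorTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            task=self.task,
            group=None if self.group is None else self.group[idx],
            positive_label=self.positive_label,
            code_maps=dict(self.code_maps),
        )

    def to_frame(self, target_column: str = "y", group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        df[target_column] = self.y
        if self.group is not None:
            df[group_column] = self.group
        return df


def read_table(
    path,
    target_column: str,
    group_column: str | None = None,
    task: str = "regression",
    categorical_columns: list[str] | None = None,
    positive_label: object | None = None,
    sep: str | None = None,
    on_missing: str = "error",
) -> DescriptorTable:
    """Load a delimited descriptor table.

    The first column is taken as the sample id. All remaining columns other
    than the target and group must be numeric unless declared in
    ``categorical_columns``, in which case they are integer-encoded (codes
    assigned in sorted value order) and the code map recorded.

    ``on_missing``: ``"error"`` rejects tables with missing values (the
    default — curated descriptor tables are complete); ``"drop"`` drops the
    offending rows and logs how many.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("table must have a sample-id column and at least one more")
    id_col = df.columns[0]
    if target_column not in df.columns:
        raise ValueError(f"target column {target_column!r} not found in {path}")
    if group_column is not None and group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path}")

    sample_ids = df[id_col].tolist()
    if len(set(map(str, sample_ids))) != len(sample_ids):
        raise ValueError("duplicate sample ids in input table")

    categorical_columns = list(categorical_columns or [])
    feature_cols = [
        c for c in df.columns
        if c not in (id_col, target_column, group_column)
    ]

    code_maps: dict[str, dict] = {}
    feats = df[feature_cols].copy()
    for col in feature_cols:
        if col in categorical_columns:
            values = sorted(feats[col].dropna().unique(), key=str)
            mapping = {v: i for i, v in enumerate(values)}
            feats[col] = feats[col].map(mapping)
            code_maps[col] = mapping
        elif not pd.api.types.is_numeric_dtype(feats[col]):
            raise ValueError(
                f"column {col!r} is non-numeric; declare it in categorical_columns"
            )

    mask = feats.notna().all(axis=1) & df[target_column].notna()
    if not mask.all():
        n_bad = int((~mask).sum())
        if on_missing == "drop":
            logger.warning("dropping %d rows with missing values", n_bad)
            feats = feats[mask]
            df = df[mask]
            sample_ids = df[id_col].tolist()
        else:
            raise ValueError(
                f"{n_bad} rows contain missing values (use on_missing='drop' to drop them)"
            )

    y = df[target_column].to_numpy()
    if positive_label is None and task == "classification":
        positive_label = sorted(np.unique(y), key=str)[-1]
    return DescriptorTable(
        sample_ids=sample_ids,
        feature_names=feature_cols,
        X=feats.to_numpy(dtype=float),
        y=y,
        task=task,
        group=None if group_column is None else df[group_column].to_numpy(),
        positive_label=positive_label if positive_label is not None else 1,
        code_maps=code_maps,
    )


def write_table(table: DescriptorTable, path, target_column: str = "y",
                group_column: str = "group", sep: str | None = None) -> None:
    """Write a table in the same dialect :func:`read_table` consumes.

    Floats round-trip exactly (written with full repr precision).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table.to_frame(target_column, group_column).to_csv(path, sep=sep, index=False)


def _split_sizes(n: int, train_ratio: float) -> tuple[int, int]:
    n_train = int(np.floor(train_ratio * n))
    return n_train, n - n_train


def split_train_test(
    table: DescriptorTable,
    train_ratio: float = 0.75,
    stratify: str = "none",
    seed: int = 0,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Random disjoint train/test partition.

    Train size is floor(train_ratio * n); the remainder is the test set, so a
    3:1 split of 3786 samples gives the conventional 2839/947 partition.
    ``stratify`` is ``"none"`` (plain random, the default), ``"by_group"``
    (the ratio applied within each group label, remainders assigned at
    random), or ``"by_class"`` (same, within each target class). Groups or
    classes with fewer than 2 samples are warned about and sent to train.
    """
    if not 0.0 < train_ratio < 1.0:
        raise ValueError("train_ratio must lie strictly between 0 and 1")
    if stratify not in ("none", "by_group", "by_class"):
        raise ValueError(f"unknown stratify mode {stratify!r}")
    rng = np.random.default_rng(seed)
    n = table.n_samples

    if stratify == "none":
        perm = rng.permutation(n)
        n_train, _ = _split_sizes(n, train_ratio)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        if stratify == "by_group":
            if table.group is None:
                raise ValueError("stratify='by_group' requires group labels")
            labels = table.group
        else:
            labels = table.y
        train_parts: list[np.ndarray] = []
        test_parts: list[np.ndarray] = []
        for value in sorted(np.unique(labels), key=str):
            members = np.flatnonzero(labels == value)
            if len(members) < 2:
                logger.warning(
                    "stratum %r has %d sample(s); assigning to train", value, len(members)
                )
                train_parts.append(members)
                continue
            perm = rng.permutation(members)
            k, _ = _split_sizes(len(members), train_ratio)
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        train_idx = np.sort(np.concatenate(train_parts)) if train_parts else np.array([], int)
        test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)

    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    return table.subset(train_idx), table.subset(test_idx)


def write_split_manifest(train: DescriptorTable, test: DescriptorTable, path) -> None:
    """Two-column CSV (sample_id, partition) recording a split."""
    rows = [(sid, "train") for sid in train.sample_ids]
    rows += [(sid, "test") for sid in test.sample_ids]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(path, index=False)
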