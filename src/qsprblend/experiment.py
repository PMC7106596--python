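"""End-to-end fit/evaluate runs: four level-0 models + three blends.

Produces the conventional results layout — one row per model with training
and test statistics (R²/RMSE for regression; Acc/Pr/r/F1/MCC plus the
confusion cells for classification) — as a pandas DataFrame that the CLI
writes to disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import blending, level0
from .dataset import DescriptorTable
from .metrics import MetricReport

__all__ = ["run_experiment", "ExperimentResult"]


class ExperimentResult:
    """Fitted models, per-model reports and the combined results table."""

    def __init__(self, level0_models, blenders, reports, table):
        self.level0_models = level0_models
        self.blenders = blenders
        self.reports = reports  # name -> {"train": MetricReport, "test": ...}
        self.table = table

    def __repr__(self) -> str:
        return f"<ExperimentResult: {len(self.reports)} models>\n{self.table}"


def _row(name: str, train_rep: MetricReport, test_rep: MetricReport) -> dict:
    if train_rep.task == "regression":
        return {
            "model": name,
            "train_r2": train_rep.r_squared,
            "train_rmse": train_rep.rmse,
            "test_r2": test_rep.r_squared,
            "test_rmse": test_rep.rmse,
        }
    ct = test_rep.confusion
    return {
        "model": name,
        "train_acc_pct": train_rep.acc * 100,
        "train_f1_pct": (train_rep.f1 or 0) * 100,
        "test_acc_pct": test_rep.acc * 100,
        "test_pr_pct": (test_rep.precision or 0) * 100,
        "test_r_pct": (test_rep.recall or 0) * 100,
        "test_f1_pct": (test_rep.f1 or 0) * 100,
        "test_mcc_pct": test_rep.mcc * 100,
        "a": ct.a,
        "b": ct.b,
        "c": ct.c,
        "d": ct.d,
    }


def _evaluate_level0(model, table: DescriptorTable) -> MetricReport:
    from .metrics import classification_metrics, confusion_table, regression_metrics

    pred = level0.predict_level0(model, table)
    if table.task == "regression":
        return regression_metrics(table.y, pred)
    return classification_metrics(confusion_table(table.y, pred, table.positive_label))


def run_experiment(
    train: DescriptorTable,
    test: DescriptorTable,
    specs=None,
    variants=("uniform", "linear", "any"),
    blend_mode: str = "holdout",
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> ExperimentResult:
    """Fit the level-0 pool and the requested blend variants; score both sets."""
    if specs is None:
        specs = blending.default_specs(train.task, random_state=int(seed) % (2**31 - 1))

    fitted = {s.kind: level0.fit_level0(train, s) for s in specs}
    reports: dict[str, dict] = {}
    rows = []
    for kind, model in fitted.items():
        rep_train = _evaluate_level0(model, train)
        rep_test = _evaluate_level0(model, test)
        reports[kind] = {"train": rep_train, "test": rep_test}
        rows.append(_row(kind, rep_train, rep_test))

    blenders = {}
    for variant in variants:
        b = blending.fit_blend(
            train,
            specs=specs,
            variant=variant,
            blend_mode=blend_mode,
            holdout_fraction=holdout_fraction,
            seed=seed,
        )
        blenders[variant] = b
        name = f"{variant}_blending"
        rep_train, rep_test = b.evaluate(train), b.evaluate(test)
        reports[name] = {"train": rep_train, "test": rep_test}
        rows.append(_row(name, rep_train, rep_test))

    table = pd.DataFrame(rows).set_index("model")
    return ExperimentResult(fitted, blenders, reports, table)
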