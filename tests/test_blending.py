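"""The level-0/level-1 blending protocol: combiners, weights, invariants."""

import numpy as np
import pytest

from qsprblend.blending import (
    BlendConfig,
    Blender,
    BlendingModel,
    extract_weights,
    fit_blend,
    fit_blend_config,
    predict_blend,
)
from qsprblend.dataset import DescriptorTable
from qsprblend.level0 import FittedLevel0, Level0Spec, predict_level0
from qsprblend.metrics import rmse
from qsprblend.synthetic import SyntheticSpec, generate_regression
from conftest import FAST, fast_specs


class _StubLearner:
    """Deterministic stand-in regressor with fixed outputs (synthetic)."""

    def __init__(self, outputs):
        self.outputs = np.asarray(outputs, dtype=float)
        self.feature_importances_ = None

    def predict(self, X):
        return self.outputs[: len(X)]


def _stub_model(outputs, feature_names):
    p = len(feature_names)
    from qsprblend.importance import ImportanceProfile

    return FittedLevel0(
        spec=Level0Spec(kind="rf", task="regression"),
        learner=_StubLearner(outputs),
        importance=ImportanceProfile(feature_names=feature_names,
                                     scores=np.full(p, 1.0 / p)),
        feature_names=list(feature_names),
    )


def _stub_table(n):
    return DescriptorTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=["f0", "f1"],
        X=np.zeros((n, 2)),
        y=np.zeros(n),
        task="regression",
    )


def _uniform_blender(models):
    b = Blender(
        variant="uniform", level0=models, level1=None,
        blend_mode="insample", holdout_fraction=0.2, task="regression",
    )
    b.weights = extract_weights(b)
    return b


class TestConfigValidation:
    def test_fewer_than_two_models_rejected(self):
        with pytest.raises(ValueError, match="two level-0"):
            BlendConfig(specs=[Level0Spec(kind="rf")])

    def test_bad_holdout_fraction_rejected(self):
        specs = [Level0Spec(kind="rf"), Level0Spec(kind="gbm")]
        with pytest.raises(ValueError, match="holdout_fraction"):
            BlendConfig(specs=specs, blend_mode="holdout", holdout_fraction=0.7)

    def test_unknown_variant_rejected(self):
        specs = [Level0Spec(kind="rf"), Level0Spec(kind="gbm")]
        with pytest.raises(ValueError, match="variant"):
            BlendConfig(specs=specs, variant="stacked")


class TestUniformPrediction:
    def test_hand_arithmetic_mean(self):
        models = [
            _stub_model([1.0, 3.0], ["f0", "f1"]),
            _stub_model([3.0, 5.0], ["f0", "f1"]),
        ]
        blender = _uniform_blender(models)
        assert np.allclose(predict_blend(blender, _stub_table(2)), [2.0, 4.0])

    def test_equals_elementwise_mean_of_level0(self, reg_table):
        table, _ = reg_table
        blender = fit_blend(table, specs=fast_specs("regression"), variant="uniform")
        stack = np.column_stack(
            [predict_level0(m, table) for m in blender.level0]
        )
        assert np.array_equal(predict_blend(blender, table), stack.mean(axis=1))

    def test_unanimous_vote_positive(self, clf_table):
        table, _ = clf_table
        blender = fit_blend(
            table, specs=fast_specs("classification"), variant="uniform"
        )
        votes = np.column_stack([predict_level0(m, table) for m in blender.level0])
        unanimous = (votes == 1).all(axis=1)
        pred = predict_blend(blender, table)
        assert (pred[unanimous] == 1).all()

    def test_tie_breaks_by_mean_probability(self):
        """2-2 vote with mean positive probability 0.6 resolves positive."""

        class _StubClf:
            def __init__(self, label, proba):
                self.classes_ = np.array([0, 1])
                self._label, self._proba = label, proba

            def predict(self, X):
                return np.full(len(X), self._label)

            def predict_proba(self, X):
                return np.column_stack(
                    [np.full(len(X), 1 - self._proba), np.full(len(X), self._proba)]
                )

        from qsprblend.importance import ImportanceProfile

        def mk(label, proba):
            return FittedLevel0(
                spec=Level0Spec(kind="rf", task="classification"),
                learner=_StubClf(label, proba),
                importance=ImportanceProfile(["f0", "f1"], np.array([0.5, 0.5])),
                feature_names=["f0", "f1"],
                classes_=np.array([0, 1]),
                positive_label=1,
            )

        models = [mk(1, 0.9), mk(1, 0.8), mk(0, 0.4), mk(0, 0.3)]  # mean p = 0.6
        b = Blender(
            variant="uniform", level0=models, level1=None,
            blend_mode="insample", holdout_fraction=0.2,
            task="classification", positive_label=1, negative_label=0,
        )
        b.weights = extract_weights(b)
        table = _stub_table(3)
        assert (predict_blend(b, table) == 1).all()


class TestWeights:
    def test_uniform_weights_are_quarter_each(self, reg_table):
        table, _ = reg_table
        blender = fit_blend(table, specs=fast_specs("regression"), variant="uniform")
        assert np.allclose(blender.weights, 0.25)

    def test_linear_coefficients_normalized_by_hand(self):
        class _Lin:
            coef_ = np.array([1.0, 2.0, 1.0])

        b = Blender(
            variant="linear", level0=[None, None, None], level1=_Lin(),
            blend_mode="insample", holdout_fraction=0.2, task="regression",
        )
        assert np.allclose(extract_weights(b), [0.25, 0.5, 0.25])

    @pytest.mark.parametrize("variant", ["uniform", "linear", "any"])
    @pytest.mark.parametrize("task", ["regression", "classification"])
    def test_all_variants_on_simplex(self, variant, task, reg_table, clf_table):
        table, _ = reg_table if task == "regression" else clf_table
        blender = fit_blend(table, specs=fast_specs(task), variant=variant, seed=0)
        w = blender.weights
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_coefficients_fall_back_to_uniform(self):
        class _Lin:
            coef_ = np.zeros(4)

        b = Blender(
            variant="linear", level0=[None] * 4, level1=_Lin(),
            blend_mode="insample", holdout_fraction=0.2, task="regression",
        )
        with pytest.warns(UserWarning, match="zero"):
            w = extract_weights(b)
        assert np.allclose(w, 0.25)


class TestFitting:
    def test_same_seed_identical_weights_any_variant(self, reg_table):
        table, _ = reg_table
        w1 = fit_blend(table, specs=fast_specs("regression"), variant="any", seed=3).weights
        w2 = fit_blend(table, specs=fast_specs("regression"), variant="any", seed=3).weights
        assert np.array_equal(w1, w2)

    def test_collinear_level0_linear_blend_is_symmetric(self, reg_table):
        """Two identical level-0 models: the combiner splits weight evenly
        and its output is a perfect affine function of the shared prediction
        (OLS collapses the collinear pair to a single calibrated signal)."""
        table, _ = reg_table
        specs = [
            Level0Spec(kind="rf", hyperparameters=FAST, random_state=1),
            Level0Spec(kind="rf", hyperparameters=FAST, random_state=1),
        ]
        blender = fit_blend(table, specs=specs, variant="linear",
                            blend_mode="insample")
        assert np.allclose(blender.weights, [0.5, 0.5])
        single = predict_level0(blender.level0[0], table)
        blend = predict_blend(blender, table)
        # exact affine relationship: residual of blend ~ single fit is zero
        coeffs = np.polyfit(single, blend, 1)
        assert np.allclose(np.polyval(coeffs, single), blend, atol=1e-8)

    def test_degenerate_level1_falls_back_to_uniform(self):
        """A single-class level-1 training window triggers the uniform fallback."""
        from qsprblend import blending as bl

        cfg = BlendConfig(specs=fast_specs("classification"), variant="linear",
                          blend_mode="insample")
        with pytest.warns(UserWarning, match="single-class"):
            model, fallback = bl._fit_level1(
                cfg, "classification", np.zeros((30, 4)), np.ones(30), seed=0,
                positive_label=1,
            )
        assert fallback and model is None

    def test_insample_linear_blend_beats_best_level0_on_train(self, reg_table):
        """OLS over the level-0 predictions cannot lose to any single model
        in-sample (its span contains each of them)."""
        table, _ = reg_table
        blender = fit_blend(
            table, specs=fast_specs("regression"), variant="linear",
            blend_mode="insample",
        )
        blend_rmse = rmse(table.y, predict_blend(blender, table))
        level0_rmses = [
            rmse(table.y, predict_level0(m, table)) for m in blender.level0
        ]
        assert blend_rmse <= min(level0_rmses) + 1e-9

    def test_importance_is_weighted_blend_of_level0_profiles(self, reg_table):
        table, _ = reg_table
        blender = fit_blend(table, specs=fast_specs("regression"), variant="any", seed=1)
        manual = np.zeros(table.n_features)
        for w, m in zip(blender.weights, blender.level0):
            manual += w * m.importance.scores
        assert np.allclose(blender.importance.scores, manual)

    def test_model_results_interface(self, reg_table):
        table, _ = reg_table
        model = BlendingModel(table, specs=fast_specs("regression"), variant="uniform")
        result = model.fit(seed=0)
        report = result.evaluate(table)
        assert report.task == "regression" and report.rmse >= 0
        text = result.summary()
        assert "uniform blending" in text and "bagged_full_trees" in text

    def test_fit_blend_config_reseeds_level0(self, reg_table):
        table, _ = reg_table
        cfg = BlendConfig(specs=fast_specs("regression"), variant="uniform")
        b = fit_blend_config(table, cfg, seed=17)
        assert all(m.spec.random_state == 17 for m in b.level0)

    def test_save_writes_weights_and_models(self, tmp_path, reg_table):
        import json

        table, _ = reg_table
        blender = fit_blend(table, specs=fast_specs("regression"), variant="linear")
        out = tmp_path / "blend"
        blender.save(out)
        weights = json.loads((out / "weights.json").read_text())
        assert len(weights) == 4
        assert sum(weights.values()) == pytest.approx(1.0)
        assert (out / "level1.joblib").exists()


class TestConvexityInvariant:
    def test_uniform_rmse_bounded_by_worst_level0_100_trials(self, reg_table):
        """Jensen: mean-prediction RMSE never exceeds the worst level-0 RMSE,
        checked on 100 independently generated evaluation sets."""
        train, _ = reg_table
        blender = fit_blend(train, specs=fast_specs("regression"), variant="uniform")
        for trial in range(100):
            spec = SyntheticSpec(
                n_samples=40, n_features=train.n_features, n_informative=3,
                noise_sd=0.3, nonlinearity="none", seed=10_000 + trial,
            )
            eval_table, _ = generate_regression(spec)
            blend_rmse = rmse(eval_table.y, predict_blend(blender, eval_table))
            worst = max(
                rmse(eval_table.y, predict_level0(m, eval_table))
                for m in blender.level0
            )
            assert blend_rmse <= worst + 1e-12
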