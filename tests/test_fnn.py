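"""Regressor: architecture, metrics, early stopping, CV, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digestnn import (
    AugmentationConfig,
    ProteinFeatureTable,
    RegressorSpec,
    SyntheticConfig,
    TrainConfig,
    TrainedRegressor,
    augment_ensemble,
    build_regressor,
    evaluate,
    generate_protein_table,
    kfold_cv,
    train,
    train_regressor,
)
from digestnn.augmentation import GANConfig, VAEConfig
from digestnn.exceptions import ConfigError, DataError, FoldError, ShapeError
from digestnn.synthetic import table3_fixture


class TestArchitecture:
    @pytest.mark.parametrize("spec,count", [
        (RegressorSpec.full(), 11 * 128 + 128 + 128 * 64 + 64 + 64 * 32 + 32 + 32 + 1),
        (RegressorSpec.simplified(), 3 * 128 + 128 + 128 * 64 + 64 + 64 * 32 + 32 + 32 + 1),
    ])
    def test_parameter_count_formula(self, spec, count):
        model = build_regressor(spec, seed=0)
        assert spec.n_params == count == model.n_params

    def test_same_seed_same_initial_weights(self):
        a = build_regressor(RegressorSpec.full(), seed=5)
        b = build_regressor(RegressorSpec.full(), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_invalid_spec(self):
        with pytest.raises(ConfigError):
            RegressorSpec(feature_names=("no_such_feature",))
        with pytest.raises(ConfigError):
            RegressorSpec(hidden=(128, 64))


class TestEvaluate:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_loop(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        p = y + rng.normal(scale=0.5, size=12)
        rep = evaluate(y, p)
        mae = sum(abs(a - b) for a, b in zip(y, p)) / 12
        mse = sum((a - b) ** 2 for a, b in zip(y, p)) / 12
        sst = sum((a - np.mean(y)) ** 2 for a in y)
        assert abs(rep.mae - mae) < 1e-12
        assert abs(rep.mse - mse) < 1e-12
        assert abs(rep.rmse - np.sqrt(mse)) < 1e-12
        assert abs(rep.r2 - (1 - sum((a - b) ** 2 for a, b in zip(y, p)) / sst)) < 1e-12
        assert rep.mae <= rep.rmse + 1e-12  # Jensen

    def test_perfect_and_mean_predictions(self):
        y = np.array([0.2, 0.5, 0.8])
        perfect = evaluate(y, y)
        assert perfect.mae == 0.0 and perfect.r2 == pytest.approx(1.0)
        mean = evaluate(y, np.full(3, y.mean()))
        assert mean.r2 == pytest.approx(0.0)

    def test_literature_columns_metrics(self):
        rows = table3_fixture()
        measured = [r.digestibility for r in rows]
        predicted = [r.prediction for r in rows]
        rep = evaluate(measured, predicted)
        assert rep.mae == pytest.approx(4.74, abs=0.005)
        assert rep.rmse == pytest.approx(5.82, abs=0.005)

    def test_errors(self):
        with pytest.raises(DataError):
            evaluate([1.0], [1.0])
        with pytest.raises(DataError):
            evaluate([2.0, 2.0], [1.0, 3.0])
        with pytest.raises(ShapeError):
            evaluate([1.0, 2.0], [1.0])


class TestTraining:
    def test_patience_arithmetic(self, dataset0):
        # an unbeatable improvement threshold: epoch 1 sets the best, epochs
        # 2..16 are 15 consecutive non-improvements -> stop at epoch 16
        cfg = TrainConfig(epochs=50, improvement_threshold=1e9, seed=0)
        model = build_regressor(RegressorSpec.full(), seed=0)
        trained = train(model, dataset0, cfg)
        assert trained.stopped_epoch == 16
        assert len(trained.loss_history) == 16

    def test_training_reduces_monitored_loss(self, trained_full):
        history = trained_full.loss_history
        assert min(h[1] for h in history) < history[0][1]
        assert trained_full.stopped_epoch <= 300

    def test_test_metrics_in_plausible_regime(self, trained_full):
        assert trained_full.test_metrics.n == 97  # 20% of 483, rounded
        assert trained_full.test_metrics.r2 > 0.9

    def test_seed_reproducible_end_to_end(self, dataset0, trained_full):
        again = train_regressor(dataset0, RegressorSpec.full(), TrainConfig(seed=0))
        assert again.stopped_epoch == trained_full.stopped_epoch
        assert again.test_metrics.r2 == trained_full.test_metrics.r2

    def test_predict_deterministic_and_shape_checked(self, trained_full, table0):
        p1 = trained_full.predict(table0.X)
        p2 = trained_full.predict(table0.X)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (23,)
        with pytest.raises(ShapeError):
            trained_full.predict(table0.X[:, :5])

    def test_zero_weight_model_predicts_constant(self, trained_full, table0):
        model = build_regressor(trained_full.spec, seed=0)
        model.set_state([np.zeros_like(p) for p in model.params()])
        zeroed = TrainedRegressor(
            spec=trained_full.spec, model=model, scaler=trained_full.scaler,
            loss_history=((0.0, 0.0),), stopped_epoch=1, test_metrics=None,
            config=TrainConfig(epochs=2, early_stopping_patience=1))
        preds = zeroed.predict(table0.X)
        # affine form: all-zero weights leave only the (inverse-transformed) bias
        assert np.ptp(preds) == 0.0
        assert preds[0] == pytest.approx(trained_full.scaler.mean[-1])

    def test_json_round_trip(self, trained_full, table0, tmp_path):
        path = tmp_path / "model.json"
        trained_full.save(path)
        back = TrainedRegressor.load(path)
        np.testing.assert_allclose(back.predict(table0.X), trained_full.predict(table0.X),
                                   atol=1e-12)
        assert back.stopped_epoch == trained_full.stopped_epoch

    def test_literature_rows_batch_prediction(self, trained_simplified):
        rows = table3_fixture()
        X = np.array([[r.solubility, r.alpha_helix, r.random_coil] for r in rows])
        preds = trained_simplified.predict(X)
        assert preds.shape == (9,)
        assert np.isfinite(preds).all()


def _linear_target_table(seed=11):
    """A table whose digestibility is an exact linear map of the three
    simplified features — a noiseless recovery benchmark."""
    table = generate_protein_table(SyntheticConfig(seed=seed))
    df = table.data.copy()
    s = (df["solubility"] - 8.41) / (85.94 - 8.41)
    a = (df["alpha_helix"] - 15) / 10.0
    c = (df["random_coil"] - 26) / 10.0
    y = 0.35 + 0.25 * s + 0.2 * a + 0.1 * c
    df["digestibility"] = y.clip(0.0, 1.0)
    return ProteinFeatureTable(df)


class TestRecoveryAndAblation:
    def test_noiseless_linear_target_is_recovered(self):
        table = _linear_target_table()
        ds = augment_ensemble(table, AugmentationConfig(seed=11))
        trained = train_regressor(ds, RegressorSpec.simplified(), TrainConfig(seed=11))
        assert trained.test_metrics.r2 > 0.99

    def test_label_shuffle_destroys_honest_fit_but_not_leaky_fit(self, table0):
        # with the labels shuffled there is no signal; a held-out-originals
        # split must collapse, while the augmented-rows split stays high
        # because interpolated test rows share parents with training rows —
        # the replicated protocol's known optimism
        from digestnn import train_honest

        rng = np.random.default_rng(0)
        df = table0.data.copy()
        df["digestibility"] = rng.permutation(df["digestibility"].to_numpy())
        shuffled = ProteinFeatureTable(df)
        honest = train_honest(shuffled, cfg=TrainConfig(seed=0))
        assert honest.test_metrics.r2 <= 0.2
        ds = augment_ensemble(shuffled, AugmentationConfig(seed=0))
        leaky = train_regressor(ds, RegressorSpec.full(), TrainConfig(seed=0))
        assert leaky.test_metrics.r2 > honest.test_metrics.r2


class TestKFold:
    def test_fold_sizes_on_483(self, dataset0):
        cv = kfold_cv(dataset0, k=5, cfg=TrainConfig(seed=0))
        assert sorted(f.n for f in cv.folds) == [96, 96, 97, 97, 97]

    def test_summary_statistics(self, dataset0):
        cv = kfold_cv(dataset0, k=5, cfg=TrainConfig(seed=0))
        r2s = [f.r2 for f in cv.folds]
        assert cv.mean["r2"] == pytest.approx(np.mean(r2s))
        assert cv.sd["r2"] == pytest.approx(np.std(r2s, ddof=1))

    def test_perfect_fit_toy_every_fold(self):
        table = _linear_target_table(seed=12)
        ds = augment_ensemble(table, AugmentationConfig(seed=12))
        cv = kfold_cv(ds, k=5, cfg=TrainConfig(seed=12), spec=RegressorSpec.simplified())
        assert all(f.r2 > 0.99 for f in cv.folds)

    def test_too_few_rows(self, table0):
        with pytest.raises(FoldError):
            kfold_cv(ProteinFeatureTable(table0.data.iloc[:3].reset_index(drop=True)), k=5)
        with pytest.raises(FoldError):
            kfold_cv(table0, k=1)
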