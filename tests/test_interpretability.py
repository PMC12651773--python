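"""Feature attribution: weight, permutation and Shapley methods."""

import itertools
import math
from types import SimpleNamespace

import numpy as np
import pytest

from digestnn import (
    AugmentationConfig,
    RegressorSpec,
    SyntheticConfig,
    TrainConfig,
    augment_ensemble,
    compute_importance_report,
    generate_protein_table,
    permutation_importance,
    shapley_attribution,
    train_regressor,
    weight_importance,
)
from digestnn.exceptions import ConfigError, InsufficientDataError
from digestnn.interpretability import top3_contribution_share
from digestnn.synthetic import DEFAULT_TARGET_CORRELATIONS


def make_linear_model(coefs, names=None):
    """A duck-typed model: predict = X @ coefs (physical units)."""
    coefs = np.asarray(coefs, float)
    names = tuple(names or [f"f{i}" for i in range(coefs.size)])
    return SimpleNamespace(
        predict=lambda X, c=coefs: np.atleast_2d(X) @ c,
        spec=SimpleNamespace(feature_names=names),
    )


def exact_shapley(model, x, background):
    """Brute-force Shapley over all coalitions with background imputation."""
    d = x.size
    phi = np.zeros(d)

    def value(S):
        rows = background.copy()
        for j in S:
            rows[:, j] = x[j]
        return float(np.mean(model.predict(rows)))

    for j in range(d):
        others = [k for k in range(d) if k != j]
        for r in range(d):
            for S in itertools.combinations(others, r):
                w = math.factorial(len(S)) * math.factorial(d - len(S) - 1) / math.factorial(d)
                phi[j] += w * (value(S + (j,)) - value(S))
    return phi


class TestWeightImportance:
    def test_zero_and_constant_columns(self, trained_full):
        W = trained_full.first_layer_weights()
        saved = W.copy()
        try:
            W[0, :] = 0.0
            W[1, :] = -0.25
            scores = weight_importance(trained_full)
            names = trained_full.spec.feature_names
            assert scores[names[0]] == 0.0
            assert scores[names[1]] == pytest.approx(0.25)
        finally:
            W[...] = saved

    def test_dominant_synthetic_driver_in_top3(self, trained_full):
        scores = weight_importance(trained_full)
        top3 = sorted(scores, key=scores.get, reverse=True)[:3]
        assert "alpha_helix" in top3


class TestPermutationImportance:
    def test_disconnected_feature_has_exactly_zero_delta(self, trained_full, table0):
        W = trained_full.first_layer_weights()
        j = 2
        saved = W[j].copy()
        try:
            W[j, :] = 0.0
            scores = permutation_importance(trained_full, table0.X, table0.y,
                                            n_repeats=5, seed=0)
            assert scores[trained_full.spec.feature_names[j]] == 0.0
        finally:
            W[j] = saved

    def test_irrelevant_feature_concentrates_at_zero(self):
        # model ignores feature 1 entirely; at 50 repeats its |delta MSE| is
        # negligible against the baseline
        rng = np.random.default_rng(0)
        model = make_linear_model([1.0, 0.0])
        X = rng.normal(size=(60, 2))
        y = X[:, 0] + rng.normal(scale=0.3, size=60)
        baseline = np.mean((model.predict(X) - y) ** 2)
        scores = permutation_importance(model, X, y, n_repeats=50, seed=1)
        assert abs(scores["f1"]) < 0.05 * baseline

    def test_duplicated_feature_dilutes_importance(self):
        # redundancy oracle: y = x0; model A sees (x0, dup(x0)) and averages
        # them, model B sees x0 alone.  Permuting one duplicate hurts less
        # than permuting the lone informative input.
        rng = np.random.default_rng(2)
        x0 = rng.normal(size=80)
        y = x0.copy()
        model_dup = make_linear_model([0.5, 0.5])
        model_lone = make_linear_model([1.0, 0.0])
        X = np.column_stack([x0, x0])
        s_dup = permutation_importance(model_dup, X, y, n_repeats=30, seed=3)
        s_lone = permutation_importance(model_lone, X, y, n_repeats=30, seed=3)
        assert s_dup["f0"] < s_lone["f0"]
        assert s_dup["f1"] < s_lone["f0"]

    def test_single_row_rejected(self, trained_full, table0):
        with pytest.raises(InsufficientDataError):
            permutation_importance(trained_full, table0.X[:1], table0.y[:1])

    def test_synthetic_top_driver_has_largest_delta(self, trained_full, table0):
        scores = permutation_importance(trained_full, table0.X, table0.y, seed=0)
        assert max(scores, key=scores.get) == "alpha_helix"


class TestShapley:
    def test_additive_model_matches_closed_form_and_bruteforce(self):
        rng = np.random.default_rng(4)
        coefs = np.array([2.0, -1.5, 0.75])
        model = make_linear_model(coefs)
        background = rng.normal(size=(16, 3))
        x = np.array([1.2, -0.4, 0.9])
        phi, base = shapley_attribution(model, x[None, :], background,
                                        n_samples_per_point=512, seed=5)
        closed = coefs * (x - background.mean(axis=0))
        np.testing.assert_allclose(phi[0], closed, atol=1e-3)
        np.testing.assert_allclose(phi[0], exact_shapley(model, x, background), atol=1e-3)
        assert base == pytest.approx(float(np.mean(model.predict(background))))

    def test_efficiency_on_trained_model(self, trained_full, table0):
        phi, base = shapley_attribution(trained_full, table0.X[:8], table0.X,
                                        n_samples_per_point=256, seed=0)
        preds = trained_full.predict(table0.X[:8])
        resid = np.abs(preds - base - phi.sum(axis=1))
        assert resid.max() < 1e-2

    def test_symmetry_of_interchangeable_features(self):
        rng = np.random.default_rng(6)
        model = make_linear_model([1.0, 1.0])
        background = rng.normal(size=(200, 1))
        background = np.column_stack([background, background[::-1]])
        x = np.array([[0.7, 0.7]])
        phi, _ = shapley_attribution(model, x, background,
                                     n_samples_per_point=2000, seed=7)
        assert abs(phi[0, 0] - phi[0, 1]) < 1e-2

    def test_constant_model(self):
        model = SimpleNamespace(predict=lambda X: np.full(np.atleast_2d(X).shape[0], 3.5),
                                spec=SimpleNamespace(feature_names=("a", "b")))
        phi, base = shapley_attribution(model, np.zeros((2, 2)), np.ones((5, 2)),
                                        n_samples_per_point=64, seed=0)
        np.testing.assert_allclose(phi, 0.0)
        assert base == pytest.approx(3.5)

    def test_empty_background_rejected(self, trained_full):
        with pytest.raises(ConfigError):
            shapley_attribution(trained_full, np.zeros((1, 11)), np.zeros((0, 11)))

    def test_high_alpha_helix_pushes_prediction_up(self, trained_full, table0):
        phi, _ = shapley_attribution(trained_full, table0.X, table0.X,
                                     n_samples_per_point=128, seed=1)
        j = trained_full.spec.feature_names.index("alpha_helix")
        hi = table0.X[:, j] > table0.X[:, j].mean()
        assert phi[hi, j].mean() > 0


@pytest.fixture(scope="module")
def dominant_driver_model():
    # a table where alpha-helix is the single overwhelming driver
    targets = {name: 0.05 for name in DEFAULT_TARGET_CORRELATIONS}
    targets["alpha_helix"] = 0.9
    cfg = SyntheticConfig(seed=21, target_correlations=targets,
                          group_correlations={})
    table = generate_protein_table(cfg)
    ds = augment_ensemble(table, AugmentationConfig(seed=21))
    model = train_regressor(ds, RegressorSpec.full(), TrainConfig(seed=21))
    return model, table


class TestRankConsistency:
    def test_all_three_methods_agree_on_top_feature(self, dominant_driver_model):
        model, table = dominant_driver_model
        report = compute_importance_report(model, table.X, table.y, seed=2)
        assert report.rankings["weight"][0] == "alpha_helix"
        assert report.rankings["permutation"][0] == "alpha_helix"
        assert report.rankings["shap"][0] == "alpha_helix"

    def test_top3_share_definition(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 1.0, "e": -5.0}
        # negatives floored at zero for the share only
        assert top3_contribution_share(scores) == pytest.approx(6.0 / 7.0)
        assert top3_contribution_share({"a": -1.0, "b": -2.0}) == 0.0

    def test_report_keys_are_feature_names(self, trained_full, table0):
        report = compute_importance_report(trained_full, table0.X, table0.y,
                                           n_shap_samples=64, seed=0)
        names = set(trained_full.spec.feature_names)
        assert set(report.weight) == names == set(report.permutation) == set(report.shap_mean_abs)
        assert 0.0 <= report.top3_share <= 1.0
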