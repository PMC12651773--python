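"""Augmentation ensemble: bookkeeping, convexity, generator fidelity."""

import numpy as np
import pytest

from digestnn import (
    AugmentationConfig,
    SyntheticConfig,
    fit_sample_gan,
    fit_sample_vae,
    generate_protein_table,
    knn_generate,
    mixup_generate,
    standardize,
    augment_ensemble,
)
from digestnn.augmentation import GANConfig, VAEConfig
from digestnn.exceptions import ConfigError, InsufficientDataError


@pytest.fixture(scope="module")
def Z(table0):
    z, _ = standardize(table0)
    return z


class TestConfig:
    def test_default_counts_sum_to_460(self):
        cfg = AugmentationConfig()
        assert cfg.generated_count == 460
        cfg.validate_for(23)  # 23 * (21 - 1)

    def test_count_mismatch_rejected_before_training(self, table0):
        cfg = AugmentationConfig(mixup_count=449)
        with pytest.raises(ConfigError, match="counts sum"):
            augment_ensemble(table0, cfg)

    def test_scaled_counts(self):
        cfg = AugmentationConfig.scaled(23, 2)
        assert cfg.generated_count == 23
        assert cfg.mixup_count >= 21  # mixup dominates, remainder goes there

    @pytest.mark.parametrize("kwargs", [
        {"mixup_count": -1},
        {"knn_alpha_range": (0.0, 0.9)},
        {"knn_alpha_range": (0.9, 0.1)},
        {"mixup_alpha": 0.0},
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ConfigError):
            AugmentationConfig(**kwargs)


class TestMixup:
    def test_outputs_within_parent_bounds(self, Z):
        rows = mixup_generate(Z, alpha=0.3, count=500, seed=0)
        assert rows.shape == (500, 12)
        # convex combinations cannot leave the global per-dimension envelope
        assert (rows >= Z.min(axis=0) - 1e-12).all()
        assert (rows <= Z.max(axis=0) + 1e-12).all()

    def test_two_row_dataset_stays_on_segment(self):
        data = np.array([[0.0, 0.0], [1.0, 2.0]])
        rows = mixup_generate(data, alpha=0.3, count=200, seed=1)
        # every output is lam*a + (1-lam)*b: second coordinate is twice the first
        np.testing.assert_allclose(rows[:, 1], 2 * rows[:, 0], atol=1e-12)

    def test_identical_parents_reproduce_the_point(self):
        data = np.array([[1.5, -2.0], [1.5, -2.0]])
        rows = mixup_generate(data, count=10, seed=2)
        np.testing.assert_allclose(rows, np.tile(data[0], (10, 1)))

    def test_insufficient_rows(self):
        with pytest.raises(InsufficientDataError):
            mixup_generate(np.zeros((1, 12)), count=1)


class TestKNN:
    def test_output_on_segment_with_alpha_in_range(self):
        data = np.array([[0.0] * 12, [1.0] * 12])
        rows = knn_generate(data, k_neighbors=20, count=50, seed=3)
        # base + alpha*(neighbor-base): every coordinate equal, alpha in [0.1, 0.9]
        alphas = rows[:, 0]
        np.testing.assert_allclose(rows, np.tile(alphas[:, None], (1, 12)))
        frac = np.minimum(alphas, 1 - alphas)  # distance from nearer endpoint
        assert (frac >= 0.1 - 1e-12).all()

    def test_identical_rows_interpolate_to_same_point(self):
        data = np.tile(np.array([[2.0] * 12]), (3, 1))
        rows = knn_generate(data, count=5, seed=0)
        np.testing.assert_allclose(rows, np.tile(data[0], (5, 1)))

    def test_count_and_hull(self, Z):
        rows = knn_generate(Z, k_neighbors=20, count=2, seed=4)
        assert rows.shape == (2, 12)
        assert (rows >= Z.min(axis=0) - 1e-12).all()
        assert (rows <= Z.max(axis=0) + 1e-12).all()

    def test_k_capped_below_n(self, Z):
        # 23 rows, k=20 needs capping logic only for smaller inputs
        rows = knn_generate(Z[:5], k_neighbors=20, count=3, seed=5)
        assert rows.shape == (3, 12)

    def test_insufficient_rows(self):
        with pytest.raises(InsufficientDataError):
            knn_generate(np.zeros((1, 12)), count=1)


class TestVAE:
    def test_zero_count_trains_and_returns_empty(self, Z):
        out = fit_sample_vae(Z, VAEConfig(epochs=5), 0, seed=0)
        assert out.shape == (0, 12)

    def test_deterministic(self, Z):
        a = fit_sample_vae(Z, VAEConfig(epochs=30), 10, seed=1)
        b = fit_sample_vae(Z, VAEConfig(epochs=30), 10, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_distribution_fidelity(self, Z):
        # prior samples must resemble the training distribution
        out = fit_sample_vae(Z, VAEConfig(), 100, seed=0)
        assert np.abs(out.mean(axis=0) - Z.mean(axis=0)).max() <= 0.5
        assert (out.std(axis=0) >= 0.3).all() and (out.std(axis=0) <= 2.0).all()

    def test_insufficient_rows_for_sampling(self, Z):
        with pytest.raises(InsufficientDataError):
            fit_sample_vae(Z[:3], VAEConfig(epochs=5), 4, seed=0)


class TestGAN:
    def test_zero_count_trains_and_returns_empty(self, Z):
        out = fit_sample_gan(Z, GANConfig(epochs=5), 0, seed=0)
        assert out.shape == (0, 12)

    def test_samples_finite_and_clamped(self, Z):
        out = fit_sample_gan(Z, GANConfig(), 50, seed=2)
        assert np.isfinite(out).all()
        assert (np.abs(out) <= 6.0).all()

    def test_distribution_fidelity(self, Z):
        # adversarial training on 23 rows is unstable, so the band is looser
        # than the VAE's
        out = fit_sample_gan(Z, GANConfig(), 100, seed=0)
        assert np.abs(out.mean(axis=0) - Z.mean(axis=0)).max() <= 1.0

    def test_deterministic(self, Z):
        a = fit_sample_gan(Z, GANConfig(epochs=30), 10, seed=1)
        b = fit_sample_gan(Z, GANConfig(epochs=30), 10, seed=1)
        np.testing.assert_array_equal(a, b)


class TestEnsemble:
    def test_row_count_and_tags(self, dataset0):
        assert len(dataset0) == 483
        assert dataset0.tag_counts() == {
            "original": 23, "vae": 4, "gan": 4, "mixup": 450, "knn": 2}

    def test_originals_appear_exactly_once(self, table0, dataset0):
        z, _ = standardize(table0)
        np.testing.assert_allclose(dataset0.matrix[:23], z, atol=1e-12)
        assert (dataset0.provenance[:23] == "original").all()

    def test_interpolators_stay_in_original_hull(self, dataset0):
        z = dataset0.matrix[dataset0.provenance == "original"]
        for tag in ("mixup", "knn"):
            rows = dataset0.matrix[dataset0.provenance == tag]
            assert (rows >= z.min(axis=0) - 1e-9).all()
            assert (rows <= z.max(axis=0) + 1e-9).all()

    def test_generated_distribution_report(self, dataset0):
        gen = dataset0.matrix[dataset0.provenance != "original"]
        assert np.abs(gen.mean(axis=0)).max() <= 0.3
        assert (gen.std(axis=0) >= 0.5).all() and (gen.std(axis=0) <= 1.5).all()
        report = dataset0.distribution_report
        np.testing.assert_allclose(report["generated_mean"], gen.mean(axis=0))

    def test_deterministic_end_to_end(self, table0, dataset0):
        again = augment_ensemble(table0, AugmentationConfig(seed=0))
        np.testing.assert_array_equal(dataset0.matrix, again.matrix)
        assert (dataset0.provenance == again.provenance).all()

    def test_factor_two_scaled(self):
        table = generate_protein_table(SyntheticConfig(seed=2))
        cfg = AugmentationConfig(expansion_factor=2, mixup_count=21, vae_count=1,
                                 gan_count=1, knn_count=0,
                                 vae=VAEConfig(epochs=20), gan=GANConfig(epochs=20))
        ds = augment_ensemble(table, cfg)
        assert len(ds) == 46

    def test_round_trip_to_physical_units(self, table0, dataset0):
        phys = dataset0.original_units()
        np.testing.assert_allclose(phys[:23], table0.Xy, atol=1e-9)
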