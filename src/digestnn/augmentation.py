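"""Ensemble data augmentation: VAE, least-squares GAN, Mixup and KNN.

A 23-isolate table is far too small to train a neural regressor directly, so
the pipeline expands it 20-fold (to 483 rows) with four generators applied to
the standardized joint vector of the 11 features plus the digestibility label:

* a variational autoencoder (10-dim Gaussian latent, 3-layer encoder/decoder)
  sampled from its prior,
* a least-squares GAN whose generator/discriminator mirror the VAE widths,
* Mixup — convex combinations of random sample pairs with a Beta(0.3, 0.3)
  mixing weight shared between features and label — which contributes the
  bulk of the new rows (450 of 460 at defaults),
* KNN interpolation — a step of size U(0.1, 0.9) from a random sample toward
  one of its 20 nearest neighbors (Euclidean distance on the standardized
  features).

Default counts are vae 4, gan 4, mixup 450, knn 2: together 460 new rows,
which with the 23 originals gives the 483-row training set.  All four
generators run on the joint 12-dimensional vector so every augmented row
carries a label; Mixup makes this choice unavoidable (it mixes labels by
construction) and the others follow for consistency.

Generated rows are clamped to +-6 standardized units as a numerical sanity
bound; Mixup and KNN rows lie in the convex hull of the originals by
construction and are never affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigError, InsufficientDataError
from .feature_table import (
    CSV_COLUMNS,
    FEATURE_NAMES,
    TARGET_NAME,
    ProteinFeatureTable,
    ScalerParams,
    standardize,
)
from .nn import MLP, Adam, mse_loss

#: Clamp for generator outputs, in standardized units.
SAMPLE_CLAMP = 6.0

PROVENANCE_LEVELS = ("original", "vae", "gan", "mixup", "knn")


@dataclass(frozen=True)
class VAEConfig:
    """Variational-autoencoder hyperparameters (3-layer encoder and decoder).

    ``kl_weight`` scales the KL regularizer against the (feature-summed)
    reconstruction error; the 0.5 default keeps prior samples from
    collapsing toward the data mean on ~23-row training sets while still
    regularizing the latent.  0 gives a plain autoencoder (pure-MSE mode).
    """

    latent_dim: int = 10
    hidden: tuple[int, int] = (64, 32)
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 8
    kl_weight: float = 0.5


@dataclass(frozen=True)
class GANConfig:
    """Least-squares GAN hyperparameters; widths mirror the VAE.

    Three standard small-sample stabilizers are on by default: Adam with
    beta1 = 0.5, annealed instance noise added to the discriminator's inputs
    (``instance_noise`` down to 0 over training), and an exponential moving
    average of the generator weights (``ema_decay``) used for sampling.
    Without them an adversarial pair trained on ~23 rows drifts off-center
    by 1-3 standardized units.
    """

    latent_dim: int = 10
    hidden: tuple[int, int] = (64, 32)
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 8
    gen_batch: int = 64
    adam_beta1: float = 0.5
    instance_noise: float = 1.0
    ema_decay: float = 0.99


@dataclass(frozen=True)
class AugmentationConfig:
    """Counts and generator settings for the augmentation ensemble.

    The four counts must sum to ``n * (expansion_factor - 1)`` so that the
    stacked output (originals included once each) has exactly
    ``n * expansion_factor`` rows.  The default factor of 21 stacks 460
    generated rows (a 20-fold batch of new data, 20 x 23) on top of the 23
    originals, giving the canonical 483-row training set.
    """

    expansion_factor: int = 21
    mixup_count: int = 450
    vae_count: int = 4
    gan_count: int = 4
    knn_count: int = 2
    vae: VAEConfig = field(default_factory=VAEConfig)
    gan: GANConfig = field(default_factory=GANConfig)
    mixup_alpha: float = 0.3
    knn_k: int = 20
    knn_alpha_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mixup_count", "vae_count", "gan_count", "knn_count"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.expansion_factor < 1:
            raise ConfigError("expansion_factor must be at least 1")
        lo, hi = self.knn_alpha_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("knn_alpha_range must satisfy 0 < lo < hi < 1")
        if self.mixup_alpha <= 0:
            raise ConfigError("mixup_alpha must be positive")

    @property
    def generated_count(self) -> int:
        return self.mixup_count + self.vae_count + self.gan_count + self.knn_count

    def validate_for(self, n: int) -> None:
        expected = n * (self.expansion_factor - 1)
        if self.generated_count != expected:
            raise ConfigError(
                f"generator counts sum to {self.generated_count}, but "
                f"{n} rows at expansion factor {self.expansion_factor} "
                f"require {expected} generated rows"
            )

    @classmethod
    def scaled(cls, n: int, expansion_factor: int, seed: int = 0, **kwargs) -> "AugmentationConfig":
        """Counts proportional to the defaults for a different n or factor."""
        total = n * (expansion_factor - 1)
        base = cls()
        weights = np.array([base.mixup_count, base.vae_count, base.gan_count, base.knn_count], float)
        counts = np.floor(weights / weights.sum() * total).astype(int)
        counts[0] += total - counts.sum()  # remainder goes to mixup
        return cls(expansion_factor=expansion_factor, mixup_count=int(counts[0]),
                   vae_count=int(counts[1]), gan_count=int(counts[2]),
                   knn_count=int(counts[3]), seed=seed, **kwargs)


@dataclass(frozen=True)
class AugmentedDataset:
    """Stacked originals + generated rows in standardized units.

    ``matrix`` has 12 columns (11 features then digestibility), ``provenance``
    one tag per row, ``scaler`` the parameters that standardized the original
    table (and can invert any row back to physical units).
    """

    matrix: np.ndarray
    provenance: np.ndarray
    scaler: ScalerParams
    distribution_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(FEATURE_NAMES) + 1:
            raise ConfigError("augmented matrix must have 12 columns")
        if len(self.provenance) != len(self.matrix):
            raise ConfigError("one provenance tag per row required")
        bad = set(self.provenance) - set(PROVENANCE_LEVELS)
        if bad:
            raise ConfigError(f"unknown provenance tag(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.matrix)

    def tag_counts(self) -> dict[str, int]:
        tags, counts = np.unique(self.provenance, return_counts=True)
        return dict(zip(tags.tolist(), counts.tolist()))

    def original_units(self) -> np.ndarray:
        """The stacked matrix mapped back to physical units (12 columns)."""
        return self.scaler.inverse_transform(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        """Physical-unit DataFrame with the on-disk column names + provenance."""
        phys = self.original_units()
        df = pd.DataFrame(phys[:, :-1], columns=[CSV_COLUMNS[f] for f in FEATURE_NAMES])
        df[TARGET_NAME] = phys[:, -1] * 100.0
        df["provenance"] = self.provenance
        return df


def _require_rows(data: np.ndarray, minimum: int, what: str) -> np.ndarray:
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ConfigError(f"{what} expects a 2-D matrix")
    if data.shape[0] < minimum:
        raise InsufficientDataError(f"{what} needs at least {minimum} rows, got {data.shape[0]}")
    return data


# ---------------------------------------------------------------------------
# VAE
# ---------------------------------------------------------------------------

class VAE:
    """Gaussian-latent variational autoencoder on standardized rows.

    The encoder maps a d-dimensional row through two hidden layers to the mean
    and log-variance of a ``latent_dim`` Gaussian; the decoder mirrors it.
    Training minimizes reconstruction error (summed over the d coordinates,
    averaged over the batch) plus ``kl_weight`` times the KL divergence of the
    posterior from the standard-normal prior, with Adam, full-batch.
    """

    def __init__(self, dim: int, cfg: VAEConfig, rng: np.random.Generator):
        h1, h2 = cfg.hidden
        self.cfg = cfg
        self.dim = dim
        self.encoder = MLP((dim, h1, h2, 2 * cfg.latent_dim), rng)
        self.decoder = MLP((cfg.latent_dim, h2, h1, dim), rng)

    def fit(self, data: np.ndarray, rng: np.random.Generator) -> list[float]:
        cfg = self.cfg
        opt = Adam(self.encoder.params() + self.decoder.params(), lr=cfg.learning_rate)
        losses = []
        n = data.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                x = data[order[start:start + cfg.batch_size]]
                B = x.shape[0]
                enc = self.encoder.forward(x, train=True)
                mu, logvar = enc[:, :cfg.latent_dim], enc[:, cfg.latent_dim:]
                logvar = np.clip(logvar, -10.0, 10.0)
                std = np.exp(0.5 * logvar)
                eps = rng.standard_normal(mu.shape)
                z = mu + std * eps
                recon = self.decoder.forward(z, train=True)
                diff = recon - x
                recon_loss = float((diff * diff).sum() / B)
                kl = float(-0.5 * (1.0 + logvar - mu ** 2 - np.exp(logvar)).sum() / B)
                epoch_loss += (recon_loss + cfg.kl_weight * kl) * B

                g_recon = 2.0 * diff / B
                g_z = self.decoder.backward(g_recon)
                g_mu = g_z + cfg.kl_weight * mu / B
                g_logvar = (g_z * eps * 0.5 * std
                            + cfg.kl_weight * (-0.5) * (1.0 - np.exp(logvar)) / B)
                self.encoder.backward(np.concatenate([g_mu, g_logvar], axis=1))
                opt.step(self.encoder.grads() + self.decoder.grads())
            losses.append(epoch_loss / n)
        return losses

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        if count == 0:
            return np.empty((0, self.dim))
        z = rng.standard_normal((count, self.cfg.latent_dim))
        return np.clip(self.decoder.forward(z), -SAMPLE_CLAMP, SAMPLE_CLAMP)


def fit_sample_vae(data: np.ndarray, cfg: VAEConfig, count: int, seed: int = 0) -> np.ndarray:
    """Train a VAE on standardized rows and draw ``count`` prior samples.

    The model is trained even for ``count = 0`` (smoke path); sampling is
    deterministic for a fixed seed.
    """
    data = _require_rows(data, 5 if count > 0 else 2, "VAE training")
    rng = np.random.default_rng(seed)
    vae = VAE(data.shape[1], cfg, rng)
    vae.fit(data, rng)
    return vae.sample(count, rng)


# ---------------------------------------------------------------------------
# Least-squares GAN
# ---------------------------------------------------------------------------

class LSGAN:
    """Least-squares GAN: the adversarial objective is MSE on the
    discriminator's real/fake scores (real -> 1, fake -> 0)."""

    def __init__(self, dim: int, cfg: GANConfig, rng: np.random.Generator):
        h1, h2 = cfg.hidden
        self.cfg = cfg
        self.dim = dim
        self.generator = MLP((cfg.latent_dim, h2, h1, dim), rng)
        self.discriminator = MLP((dim, h1, h2, 1), rng)

    def fit(self, data: np.ndarray, rng: np.random.Generator) -> list[float]:
        cfg = self.cfg
        betas = (cfg.adam_beta1, 0.999)
        opt_d = Adam(self.discriminator.params(), lr=cfg.learning_rate, betas=betas)
        opt_g = Adam(self.generator.params(), lr=cfg.learning_rate, betas=betas)
        self._ema = [p.copy() for p in self.generator.params()]
        n = data.shape[0]
        g_losses = []
        for epoch in range(cfg.epochs):
            sigma = cfg.instance_noise * (1.0 - epoch / cfg.epochs)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                real = data[order[start:start + cfg.batch_size]]
                B = real.shape[0]
                z = rng.standard_normal((B, cfg.latent_dim))
                fake = self.generator.forward(z)
                if sigma > 0:
                    real = real + sigma * rng.standard_normal(real.shape)
                    fake = fake + sigma * rng.standard_normal(fake.shape)
                d_real = self.discriminator.forward(real, train=True)
                _, g = mse_loss(d_real, np.ones((B, 1)))
                self.discriminator.backward(g)
                d_grads = [a.copy() for a in self.discriminator.grads()]
                d_fake = self.discriminator.forward(fake, train=True)
                _, g = mse_loss(d_fake, np.zeros_like(d_fake))
                self.discriminator.backward(g)
                for acc, extra in zip(d_grads, self.discriminator.grads()):
                    acc += extra
                opt_d.step([0.5 * a for a in d_grads])

                z = rng.standard_normal((cfg.gen_batch, cfg.latent_dim))
                fake = self.generator.forward(z, train=True)
                if sigma > 0:
                    fake = fake + sigma * rng.standard_normal(fake.shape)
                d_fake = self.discriminator.forward(fake, train=True)
                loss_g, g = mse_loss(d_fake, np.ones((cfg.gen_batch, 1)))
                epoch_loss += 0.5 * loss_g
                grad_fake = self.discriminator.backward(g)
                self.generator.backward(grad_fake)
                opt_g.step([0.5 * a for a in self.generator.grads()])
                for e, p in zip(self._ema, self.generator.params()):
                    e *= cfg.ema_decay
                    e += (1.0 - cfg.ema_decay) * p
            g_losses.append(epoch_loss)
        return g_losses

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        if count == 0:
            return np.empty((0, self.dim))
        live = self.generator.get_state()
        if getattr(self, "_ema", None) is not None:
            self.generator.set_state(self._ema)
        z = rng.standard_normal((count, self.cfg.latent_dim))
        out = np.clip(self.generator.forward(z), -SAMPLE_CLAMP, SAMPLE_CLAMP)
        self.generator.set_state(live)
        return out


def fit_sample_gan(data: np.ndarray, cfg: GANConfig, count: int, seed: int = 0) -> np.ndarray:
    """Train an LSGAN on standardized rows and draw ``count`` generator samples."""
    data = _require_rows(data, 5 if count > 0 else 2, "GAN training")
    rng = np.random.default_rng(seed)
    gan = LSGAN(data.shape[1], cfg, rng)
    gan.fit(data, rng)
    return gan.sample(count, rng)


# ---------------------------------------------------------------------------
# Mixup and KNN interpolation
# ---------------------------------------------------------------------------

def mixup_generate(data: np.ndarray, alpha: float = 0.3, count: int = 450,
                   seed: int = 0) -> np.ndarray:
    """Convex combinations of random ordered sample pairs.

    Each output row is ``lam * x_i + (1 - lam) * x_j`` for a uniformly random
    ordered pair i != j and ``lam ~ Beta(alpha, alpha)``; the label column is
    mixed with the same lam.
    """
    data = _require_rows(data, 2, "Mixup")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    i = rng.integers(0, n, size=count)
    j = rng.integers(0, n - 1, size=count)
    j = np.where(j >= i, j + 1, j)  # uniform over j != i
    lam = rng.beta(alpha, alpha, size=count)[:, None]
    return lam * data[i] + (1.0 - lam) * data[j]


def knn_generate(data: np.ndarray, k_neighbors: int = 20, count: int = 2,
                 alpha_range: tuple[float, float] = (0.1, 0.9), seed: int = 0,
                 n_feature_cols: int = len(FEATURE_NAMES)) -> np.ndarray:
    """Interpolate each new row between a random sample and one of its
    nearest neighbors.

    Neighbors are found by Euclidean distance on the first ``n_feature_cols``
    (standardized feature) columns; ``k_neighbors`` is capped at n - 1.  The
    step size alpha is uniform on ``alpha_range`` and the full row, label
    included, is interpolated identically.
    """
    data = _require_rows(data, 2, "KNN interpolation")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(data[:, :n_feature_cols])
    _, idx = nn.kneighbors(data[:, :n_feature_cols])
    neighbors = idx[:, 1:]  # drop self
    base = rng.integers(0, n, size=count)
    pick = rng.integers(0, k, size=count)
    other = neighbors[base, pick]
    alpha = rng.uniform(*alpha_range, size=count)[:, None]
    return data[base] + alpha * (data[other] - data[base])


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def augment_ensemble(table: ProteinFeatureTable, cfg: AugmentationConfig | None = None) -> AugmentedDataset:
    """Standardize a table and expand it with all four generators.

    The output stacks the originals (once each) with the configured numbers of
    VAE, GAN, Mixup and KNN rows — 483 total for a 23-row table at defaults —
    and carries a per-feature distribution report comparing generated rows to
    the originals.  Fully deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or AugmentationConfig()
    n = len(table)
    cfg.validate_for(n)
    Z, params = standardize(table)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(cfg.seed).spawn(4)]
    blocks = [Z]
    tags = [np.full(n, "original")]
    vae_rows = fit_sample_vae(Z, cfg.vae, cfg.vae_count, seed=seeds[0])
    gan_rows = fit_sample_gan(Z, cfg.gan, cfg.gan_count, seed=seeds[1])
    mix_rows = mixup_generate(Z, cfg.mixup_alpha, cfg.mixup_count, seed=seeds[2])
    knn_rows = knn_generate(Z, cfg.knn_k, cfg.knn_count, cfg.knn_alpha_range, seed=seeds[3])
    for rows, tag in ((vae_rows, "vae"), (gan_rows, "gan"), (mix_rows, "mixup"), (knn_rows, "knn")):
        blocks.append(rows)
        tags.append(np.full(len(rows), tag))
    matrix = np.vstack(blocks)
    provenance = np.concatenate(tags)
    gen = matrix[n:]
    report = {
        "original_mean": Z.mean(axis=0).tolist(),
        "original_std": Z.std(axis=0).tolist(),
        "generated_mean": gen.mean(axis=0).tolist() if len(gen) else [],
        "generated_std": gen.std(axis=0).tolist() if len(gen) else [],
        "columns": [*FEATURE_NAMES, TARGET_NAME],
    }
    return AugmentedDataset(matrix, provenance, params, report)
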