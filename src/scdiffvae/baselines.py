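"""Benchmark embeddings: standard VAE, plain autoencoder, and PCA.

The VAE and AE reuse the DiffVAE architecture (same layer sizes, batch norm,
logistic output). The VAE swaps the MMD term for the closed-form Gaussian KL
divergence; the AE is deterministic and minimises the squared reconstruction
error. PCA provides the linear baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diffvae import (
    DiffVAEConfig,
    DiffVAEModel,
    LatentMatrix,
    _as_unit_scaled_array,
    bernoulli_nll,
)
from .nn import Adam, Chain, Dense, ReLU, BatchNorm, sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineConfig",
    "gaussian_kl",
    "train_vae",
    "AEModel",
    "ae_loss",
    "train_ae",
    "pca_embed",
]


@dataclass
class BaselineConfig:
    """Architecture/optimiser settings mirroring the DiffVAE defaults."""

    kind: str = "vae"  # {"vae", "ae", "pca"}
    h1: int = 256
    h2: int | None = None
    m: int = 50
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 100
    head_activation: str = "relu"
    batchnorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2 is None:
            self.h2 = 2 * self.h1
        if self.kind not in ("vae", "ae", "pca"):
            raise ValueError("kind must be one of vae, ae, pca")

    def to_diffvae_config(self) -> DiffVAEConfig:
        return DiffVAEConfig(
            h1=self.h1,
            h2=self.h2,
            m=self.m,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            head_activation=self.head_activation,
            batchnorm=self.batchnorm,
            seed=self.seed,
        )


def gaussian_kl(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL(N(mu, diag(sigma^2)) || N(0, I)) summed over dimensions, averaged
    over the batch: 0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - log sigma_d^2)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=np.float64))
    kl = 0.5 * (mu**2 + np.exp(log_var) - 1.0 - log_var).sum(axis=1)
    return float(kl.mean())


def train_vae(expr, config: BaselineConfig) -> tuple[DiffVAEModel, LatentMatrix, list[float]]:
    """Standard VAE (ELBO with closed-form Gaussian KL), DiffVAE architecture.

    Returns (model, latent means, epoch loss history); deterministic for a
    fixed ``config.seed``.
    """
    x_all = _as_unit_scaled_array(expr)
    n = x_all.shape[0]
    cfg = config.to_diffvae_config()
    model = DiffVAEModel(x_all.shape[1], cfg)
    history: list[float] = []
    if cfg.epochs > 0:
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(model.params(), lr=cfg.learning_rate)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x = x_all[idx]
                b = x.shape[0]
                opt.zero_grad()
                h = model.encoder.forward(x, train=True)
                mu = model.head_mu.forward(h, train=True)
                log_var = model.head_logvar.forward(h, train=True)
                eps = rng.standard_normal(mu.shape)
                sig = np.exp(0.5 * log_var)
                z = mu + eps * sig
                logits = model.decoder.forward(z, train=True)
                x_prime = sigmoid(logits)
                loss = bernoulli_nll(x, x_prime) + gaussian_kl(mu, log_var)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                g_logits = (x_prime - x) / b
                g_z = model.decoder.backward(g_logits)
                g_mu = g_z + mu / b
                g_logvar = g_z * eps * sig * 0.5 + 0.5 * (np.exp(log_var) - 1.0) / b
                g_h = model.head_mu.backward(g_mu) + model.head_logvar.backward(g_logvar)
                model.encoder.backward(g_h)
                opt.step()
                total += loss * b
                seen += b
            history.append(total / seen)
            logger.info("vae epoch %d loss %.6f", epoch, history[-1])
    mu_all, _ = model.encode(x_all)
    return model, LatentMatrix(z_means=mu_all), history


class AEModel:
    """Deterministic autoencoder with the DiffVAE layer sizes.

    Encoder: two ReLU hidden layers (with batch norm) and a linear bottleneck
    of width m; decoder: the DiffVAE decoder with logistic output.
    """

    def __init__(self, n_genes: int, config: BaselineConfig) -> None:
        self.config = config
        self.n_genes = n_genes
        rng = np.random.default_rng(config.seed)
        enc: list = [Dense(rng, n_genes, config.h2)]
        if config.batchnorm:
            enc.append(BatchNorm(config.h2))
        enc.append(ReLU())
        enc.append(Dense(rng, config.h2, config.h1))
        if config.batchnorm:
            enc.append(BatchNorm(config.h1))
        enc.append(ReLU())
        enc.append(Dense(rng, config.h1, config.m))
        self.encoder = Chain(enc)
        self.decoder = Chain(
            [
                Dense(rng, config.m, config.h1),
                ReLU(),
                Dense(rng, config.h1, config.h2),
                ReLU(),
                Dense(rng, config.h2, n_genes),
            ]
        )

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return self.encoder.forward(x, train=False)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        return sigmoid(self.decoder.forward(z, train=False))

    def params(self):
        return self.encoder.params() + self.decoder.params()


def ae_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Squared reconstruction error summed over genes, averaged over the batch."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    xp = np.atleast_2d(np.asarray(x_prime, dtype=np.float64))
    return float(((x - xp) ** 2).sum(axis=1).mean())


def train_ae(expr, config: BaselineConfig) -> tuple[AEModel, LatentMatrix, list[float]]:
    """Plain autoencoder trained on mean squared error; latent = bottleneck."""
    x_all = _as_unit_scaled_array(expr)
    n = x_all.shape[0]
    model = AEModel(x_all.shape[1], config)
    history: list[float] = []
    if config.epochs > 0:
        rng = np.random.default_rng(config.seed + 1)
        opt = Adam(model.params(), lr=config.learning_rate)
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                x = x_all[idx]
                b = x.shape[0]
                opt.zero_grad()
                z = model.encoder.forward(x, train=True)
                logits = model.decoder.forward(z, train=True)
                x_prime = sigmoid(logits)
                loss = ae_loss(x, x_prime)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                g_logits = 2.0 * (x_prime - x) * x_prime * (1.0 - x_prime) / b
                g_z = model.decoder.backward(g_logits)
                model.encoder.backward(g_z)
                opt.step()
                total += loss * b
                seen += b
            history.append(total / seen)
            logger.info("ae epoch %d loss %.6f", epoch, history[-1])
    return model, LatentMatrix(z_means=model.encode(x_all)), history


def pca_embed(expr, m: int, seed: int = 0) -> LatentMatrix:
    """Top-m principal-component scores of the gene-centred unit-scaled matrix.

    Genes are centred but not re-scaled (the input is already Min-Max
    scaled). Component signs follow the convention that the loading entry of
    largest magnitude is positive.
    """
    from sklearn.decomposition import PCA

    x = _as_unit_scaled_array(expr)
    if m > min(x.shape):
        raise ValueError(f"m={m} exceeds min(N, genes)={min(x.shape)}")
    pca = PCA(n_components=m, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| entry positive per component
    for j in range(m):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
            pca.components_[j] = -load
    lat = LatentMatrix(z_means=scores)
    lat.explained_variance = pca.explained_variance_
    lat.components = pca.components_
    return lat
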