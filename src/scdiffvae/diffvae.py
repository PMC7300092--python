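"""DiffVAE: an MMD-regularised variational autoencoder for expression data.

The model is an InfoVAE-family autoencoder: a fully connected Gaussian
encoder (two ReLU hidden layers with batch normalisation, parallel heads for
the posterior mean mu and log-variance), the reparameterisation
``z = mu + eps * sigma``, and a fully connected decoder with a logistic
output so that each gene is modelled as a Bernoulli variable on [0, 1].

Training minimises

    BernoulliNLL(x, x') + mmd_weight * MMD^2(q(z), N(0, I)),

where the maximum mean discrepancy is estimated with the biased V-statistic
over a multi-bandwidth RBF kernel family, comparing the minibatch of sampled
latent codes against a fresh standard-normal batch of the same size. Unlike
the KL term of a standard VAE, the MMD term matches the *aggregate* posterior
to the isotropic prior, which preserves mutual information between input and
code and encourages disentangled latent dimensions.

The published architecture applies ReLU to both encoder heads; this is kept
as the default (``head_activation="relu"``) with a ``"linear"`` option since
ReLU heads constrain mu >= 0 and sigma >= 1.

For downstream analysis the latent representation of a cell is the posterior
mean mu (no sampling).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, BatchNorm, Chain, Dense, ReLU, sigmoid
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiffVAEConfig",
    "DiffVAEModel",
    "LatentMatrix",
    "encode",
    "reparameterize",
    "decode",
    "mmd",
    "bernoulli_nll",
    "diffvae_loss",
    "train_diffvae",
    "get_latent",
    "hyperparameter_search",
    "default_bandwidths",
    "save_model",
    "load_model",
]

_CLAMP = 1e-7  # numerical floor on logistic outputs inside the NLL


@dataclass
class DiffVAEConfig:
    """Hyperparameters; defaults are the published values for the
    hematopoietic datasets (h1=256, h2=2*h1, m=50, lr=0.001, B=128,
    100 epochs)."""

    h1: int = 256
    h2: int | None = None  # defaults to 2 * h1
    m: int = 50
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 100
    mmd_weight: float = 1.0
    kernel_bandwidths: list[float] | None = None
    head_activation: str = "relu"  # "relu" (as published) or "linear"
    batchnorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2 is None:
            self.h2 = 2 * self.h1
        if min(self.h1, self.h2, self.m, self.batch_size) <= 0 or self.epochs < 0:
            raise ValueError("all sizes must be positive and epochs >= 0")
        if self.mmd_weight < 0:
            raise ValueError("mmd_weight must be >= 0")
        if self.head_activation not in ("relu", "linear"):
            raise ValueError("head_activation must be 'relu' or 'linear'")


@dataclass
class LatentMatrix:
    """Per-cell latent means with per-dimension statistics.

    ``dim_sds`` uses the population convention (divide by N), matching the
    extreme-cell rule in :mod:`scdiffvae.celltype`.
    """

    z_means: np.ndarray
    dim_means: np.ndarray = field(default=None)
    dim_sds: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.z_means = np.asarray(self.z_means, dtype=np.float64)
        if self.dim_means is None:
            self.dim_means = self.z_means.mean(axis=0)
        if self.dim_sds is None:
            self.dim_sds = self.z_means.std(axis=0)  # population sd

    @property
    def n_cells(self) -> int:
        return self.z_means.shape[0]

    @property
    def m(self) -> int:
        return self.z_means.shape[1]


def default_bandwidths(m: int) -> list[float]:
    """Multi-kernel RBF bandwidths sqrt(m/2)*c, c in {0.1, 0.5, 1, 2, 10}.

    The scale sqrt(m/2) is the median-heuristic order of magnitude for
    distances between m-dimensional standard-normal samples.
    """
    base = np.sqrt(m / 2.0)
    return [base * c for c in (0.1, 0.5, 1.0, 2.0, 10.0)]


class DiffVAEModel:
    """Weights and architecture of a DiffVAE (see module docstring)."""

    def __init__(self, n_genes: int, config: DiffVAEConfig) -> None:
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
        self.encoder = Chain(enc)
        relu_heads = config.head_activation == "relu"
        self.head_mu = Chain([Dense(rng, config.h1, config.m)] + ([ReLU()] if relu_heads else []))
        self.head_logvar = Chain([Dense(rng, config.h1, config.m)] + ([ReLU()] if relu_heads else []))
        self.decoder = Chain(
            [
                Dense(rng, config.m, config.h1),
                ReLU(),
                Dense(rng, config.h1, config.h2),
                ReLU(),
                Dense(rng, config.h2, n_genes),
            ]
        )

    # -- forward passes -------------------------------------------------
    def encode_forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, np.ndarray]:
        h = self.encoder.forward(x, train=train)
        return self.head_mu.forward(h, train=train), self.head_logvar.forward(h, train=train)

    def decode_logits(self, z: np.ndarray, train: bool) -> np.ndarray:
        return self.decoder.forward(z, train=train)

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mu, log sigma^2) per row, inference-mode batch norm."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {x.shape[1]}")
        return self.encode_forward(x, train=False)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Reconstruction in (0, 1) per row (maximum-likelihood estimate)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != self.config.m:
            raise ValueError(f"expected latent width {self.config.m}, got {z.shape[1]}")
        return sigmoid(self.decode_logits(z, train=False))

    def params(self):
        return (
            self.encoder.params()
            + self.head_mu.params()
            + self.head_logvar.params()
            + self.decoder.params()
        )

    @property
    def decoder_weight_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The decoder's (W0, W1, W2) used for the gene-weight matrix omega."""
        dense = [l for l in self.decoder.layers if isinstance(l, Dense)]
        return dense[0].W.value, dense[1].W.value, dense[2].W.value


def encode(model: DiffVAEModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Encoder forward pass: (mu, log_var) per input row."""
    return model.encode(x)


def decode(model: DiffVAEModel, z: np.ndarray) -> np.ndarray:
    """Decoder forward pass: reconstructions strictly inside (0, 1)."""
    return model.decode(z)


def reparameterize(mu: np.ndarray, log_var: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + eps * exp(log_var / 2)."""
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    if not (np.isfinite(mu).all() and np.isfinite(log_var).all()):
        raise ValueError("non-finite inputs to reparameterize")
    return mu + np.asarray(eps) * np.exp(0.5 * log_var)


def _kernel_sums(sq: np.ndarray, bandwidths) -> np.ndarray:
    total = np.zeros_like(sq)
    for h in bandwidths:
        total += np.exp(-sq / (2.0 * h * h))
    return total


def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def mmd(sample_q: np.ndarray, sample_p: np.ndarray, bandwidths=None) -> float:
    """Biased (V-statistic) squared MMD under a multi-bandwidth RBF family.

    MMD^2 = mean K(q, q) + mean K(p, p) - 2 mean K(q, p) with
    K(a, b) = sum_h exp(-||a - b||^2 / (2 h^2)); nonnegative by construction.
    """
    q = np.atleast_2d(np.asarray(sample_q, dtype=np.float64))
    p = np.atleast_2d(np.asarray(sample_p, dtype=np.float64))
    if q.size == 0 or p.size == 0:
        raise ValueError("MMD requires non-empty batches")
    if q.shape[1] != p.shape[1]:
        raise ValueError("batches must have the same width")
    if bandwidths is None:
        bandwidths = default_bandwidths(q.shape[1])
    kqq = _kernel_sums(_pairwise_sq(q, q), bandwidths).mean()
    kpp = _kernel_sums(_pairwise_sq(p, p), bandwidths).mean()
    kqp = _kernel_sums(_pairwise_sq(q, p), bandwidths).mean()
    return float(kqq + kpp - 2.0 * kqp)


def _mmd_grad_q(q: np.ndarray, p: np.ndarray, bandwidths) -> np.ndarray:
    """Gradient of the biased squared MMD with respect to the q batch."""
    n, m_ = q.shape
    npts = p.shape[0]
    grad = np.zeros_like(q)
    dqq = q[:, None, :] - q[None, :, :]
    sqq = np.einsum("ijk,ijk->ij", dqq, dqq)
    dqp = q[:, None, :] - p[None, :, :]
    sqp = np.einsum("ijk,ijk->ij", dqp, dqp)
    for h in bandwidths:
        inv = 1.0 / (h * h)
        kqq = np.exp(-sqq * (0.5 * inv))
        kqp = np.exp(-sqp * (0.5 * inv))
        # d/dq_i mean K(q,q): both row and column occurrences -> factor 2
        grad += (-inv) * (2.0 / (n * n)) * np.einsum("ij,ijk->ik", kqq, dqq)
        grad -= (-inv) * (2.0 / (n * npts)) * np.einsum("ij,ijk->ik", kqp, dqp)
    return grad


def bernoulli_nll(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Continuous-label binary cross-entropy, summed over genes and averaged
    over the batch; x_prime is clamped to [1e-7, 1 - 1e-7]."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    xp = np.clip(np.atleast_2d(np.asarray(x_prime, dtype=np.float64)), _CLAMP, 1 - _CLAMP)
    ll = x * np.log(xp) + (1.0 - x) * np.log(1.0 - xp)
    return float(-ll.sum(axis=1).mean())


def diffvae_loss(
    x: np.ndarray,
    x_prime: np.ndarray,
    z_batch: np.ndarray,
    prior_batch: np.ndarray,
    mmd_weight: float = 1.0,
    bandwidths=None,
) -> float:
    """Training loss: Bernoulli NLL + mmd_weight * squared MMD(z, prior)."""
    return bernoulli_nll(x, x_prime) + mmd_weight * mmd(z_batch, prior_batch, bandwidths)


def _as_unit_scaled_array(expr) -> np.ndarray:
    if isinstance(expr, ExpressionMatrix):
        if expr.scale_state != "unit_scaled":
            raise ValueError("expected a unit_scaled ExpressionMatrix (run minmax_scale first)")
        return expr.values
    x = np.asarray(expr, dtype=np.float64)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("expression array must lie in [0, 1]")
    return x


def _train_step(model: DiffVAEModel, x: np.ndarray, opt: Adam, rng: np.random.Generator,
                bandwidths, mmd_weight: float) -> float:
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

    prior = rng.standard_normal(z.shape)
    loss = bernoulli_nll(x, x_prime) + mmd_weight * mmd(z, prior, bandwidths)

    # backward: fused sigmoid + cross-entropy gradient, plus the MMD term
    g_logits = (x_prime - x) / b
    g_z = model.decoder.backward(g_logits)
    if mmd_weight > 0:
        g_z = g_z + mmd_weight * _mmd_grad_q(z, prior, bandwidths)
    g_mu = g_z
    g_logvar = g_z * eps * sig * 0.5
    g_h = model.head_mu.backward(g_mu) + model.head_logvar.backward(g_logvar)
    model.encoder.backward(g_h)
    opt.step()
    return float(loss)


def train_diffvae(expr, config: DiffVAEConfig) -> tuple[DiffVAEModel, list[float]]:
    """Train a DiffVAE with minibatch Adam; returns (model, epoch loss history).

    All randomness (weight init, shuffling, reparameterisation draws, prior
    draws) flows from ``config.seed``, so identical seeds give bit-identical
    weights. The final partial minibatch of each epoch is kept. Epoch losses
    are cell-weighted means of the minibatch losses.
    """
    x_all = _as_unit_scaled_array(expr)
    n = x_all.shape[0]
    model = DiffVAEModel(x_all.shape[1], config)
    if config.epochs == 0:
        return model, []
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params(), lr=config.learning_rate)
    bandwidths = config.kernel_bandwidths or default_bandwidths(config.m)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = _train_step(model, x_all[idx], opt, rng, bandwidths, config.mmd_weight)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, step {start // config.batch_size}")
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
        logger.info("epoch %d loss %.6f", epoch, history[-1])
    return model, history


def get_latent(model: DiffVAEModel, expr) -> LatentMatrix:
    """Latent representation: the encoder's posterior mean for every cell."""
    x = _as_unit_scaled_array(expr)
    mu, _ = model.encode(x)
    return LatentMatrix(z_means=mu)


def _validation_loss(model: DiffVAEModel, x_val: np.ndarray, config: DiffVAEConfig,
                     rng: np.random.Generator) -> float:
    mu, _ = model.encode(x_val)
    x_prime = model.decode(mu)
    prior = rng.standard_normal(mu.shape)
    bandwidths = config.kernel_bandwidths or default_bandwidths(config.m)
    return diffvae_loss(x_val, x_prime, mu, prior, config.mmd_weight, bandwidths)


def hyperparameter_search(expr, grid: list[DiffVAEConfig], split_seed: int = 0):
    """Select the grid point with minimal validation loss on a seeded 80/20 split.

    Ties are broken by smaller latent size m, then smaller h1. Returns
    (best_config, results) where results maps grid index to validation loss.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    x_all = _as_unit_scaled_array(expr)
    n = x_all.shape[0]
    split_rng = np.random.default_rng(split_seed)
    order = split_rng.permutation(n)
    n_train = int(round(0.8 * n))
    x_train, x_val = x_all[order[:n_train]], x_all[order[n_train:]]
    results: list[tuple[float, int, int, int, DiffVAEConfig]] = []
    for i, cfg in enumerate(grid):
        model, _ = train_diffvae(x_train, cfg)
        val = _validation_loss(model, x_val, cfg, np.random.default_rng(split_seed + 10_000))
        results.append((val, cfg.m, cfg.h1, i, cfg))
        logger.info("grid point %d (h1=%d, m=%d, lr=%g, B=%d): val loss %.6f",
                    i, cfg.h1, cfg.m, cfg.learning_rate, cfg.batch_size, val)
    results.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    best = results[0][4]
    return best, {t[3]: t[0] for t in results}


# -- serialization ------------------------------------------------------


def save_model(model: DiffVAEModel, path) -> None:
    """Write all weights, batch-norm statistics and the config to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.config))
        f.attrs["n_genes"] = model.n_genes
        f.attrs["kind"] = "diffvae"
        for gname, chain in (
            ("encoder", model.encoder),
            ("head_mu", model.head_mu),
            ("head_logvar", model.head_logvar),
            ("decoder", model.decoder),
        ):
            grp = f.create_group(gname)
            for i, layer in enumerate(chain.layers):
                if isinstance(layer, Dense):
                    grp.create_dataset(f"{i}_W", data=layer.W.value)
                    grp.create_dataset(f"{i}_b", data=layer.b.value)
                elif isinstance(layer, BatchNorm):
                    grp.create_dataset(f"{i}_gamma", data=layer.gamma.value)
                    grp.create_dataset(f"{i}_beta", data=layer.beta.value)
                    grp.create_dataset(f"{i}_rmean", data=layer.running_mean)
                    grp.create_dataset(f"{i}_rvar", data=layer.running_var)


def load_model(path) -> DiffVAEModel:
    """Inverse of :func:`save_model`; round-trips weights losslessly."""
    import h5py

    with h5py.File(path, "r") as f:
        config = DiffVAEConfig(**json.loads(f.attrs["config"]))
        model = DiffVAEModel(int(f.attrs["n_genes"]), config)
        for gname, chain in (
            ("encoder", model.encoder),
            ("head_mu", model.head_mu),
            ("head_logvar", model.head_logvar),
            ("decoder", model.decoder),
        ):
            grp = f[gname]
            for i, layer in enumerate(chain.layers):
                if isinstance(layer, Dense):
                    layer.W.value = grp[f"{i}_W"][...]
                    layer.b.value = grp[f"{i}_b"][...]
                    layer.W.grad = np.zeros_like(layer.W.value)
                    layer.b.grad = np.zeros_like(layer.b.value)
                elif isinstance(layer, BatchNorm):
                    layer.gamma.value = grp[f"{i}_gamma"][...]
                    layer.beta.value = grp[f"{i}_beta"][...]
                    layer.running_mean = grp[f"{i}_rmean"][...]
                    layer.running_var = grp[f"{i}_rvar"][...]
    return model
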