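"""Feed-forward neural-network primitives with explicit gradients.

Dense layers, batch normalisation, ReLU and an Adam optimiser implemented on
numpy with hand-written backward passes. Everything is float64 and every
source of randomness is an explicit :class:`numpy.random.Generator`, so a
training run is bit-reproducible for a fixed seed.

These primitives back the expression autoencoders (:mod:`scdiffvae.diffvae`,
:mod:`scdiffvae.baselines`) and the graph autoencoder
(:mod:`scdiffvae.graphvae`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Dense",
    "BatchNorm",
    "ReLU",
    "Chain",
    "Adam",
    "glorot_uniform",
    "sigmoid",
]


class Parameter:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialisation for a (n_in, n_out) weight."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def sigmoid(x: np.ndarray) -> np.ndarray:
    # evaluated in two branches to stay overflow-free for large |x|
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine layer ``x @ W + b``."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        self.W = Parameter(glorot_uniform(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def params(self) -> list[Parameter]:
        return [self.W, self.b]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params(self) -> list[Parameter]:
        return []


class BatchNorm:
    """Batch normalisation with running statistics for inference.

    Training mode normalises with the minibatch mean/variance (population
    convention) and updates exponential running statistics; inference mode
    uses the running statistics, so encoding a dataset after training is a
    deterministic per-cell function.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (x, mean, inv_std, xhat)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, mean, inv_std, xhat = self._cache
        n = x.shape[0]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gxhat = g * self.gamma.value
        # standard batch-norm backward (population variance)
        gvar = (gxhat * (x - mean)).sum(axis=0) * (-0.5) * inv_std**3
        gmean = -(gxhat.sum(axis=0)) * inv_std + gvar * (-2.0 / n) * (x - mean).sum(axis=0)
        return gxhat * inv_std + gvar * 2.0 * (x - mean) / n + gmean / n

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class Chain:
    """A sequential stack of layers with forward/backward traversal."""

    def __init__(self, layers: list) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
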