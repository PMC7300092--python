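"""Graph-DiffVAE: a graph convolutional VAE predicting cell-cell links.

Cells are nodes of an undirected binary graph; node features are their
(unit-scaled) expression vectors. The initial graph connects each cell to its
most positively Pearson-correlated peer. A GCN encoder (one shared ReLU
layer, two linear heads) produces a per-node Gaussian posterior; the decoder
runs two ReLU GCN layers on [Z | X], averages its own representation Z' with
the encoder sample Z, and scores every pair through the logistic inner
product A_hat = sigmoid(Z* Z*^T). Training minimises edge-weighted Bernoulli
cross-entropy of the (self-loop-augmented) adjacency plus the closed-form
Gaussian KL, full-graph with Adam.

GCN layers use the symmetric propagation rule X' = act(A_norm X W) with
A_norm = D^-1/2 (A + I) D^-1/2 and no bias. Because the printed objective has
no class weighting but the correlation graph is very sparse, the positive
class is up-weighted by #non-edges/#edges by default (set
``edge_pos_weight=1.0`` for the unweighted objective).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Parameter, glorot_uniform, sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "CellGraph",
    "GraphDiffVAEConfig",
    "PredictedGraph",
    "correlation_graph",
    "normalize_adjacency",
    "gcn_layer",
    "GraphDiffVAEModel",
    "graph_encode",
    "graph_decode",
    "graphvae_loss",
    "train_graph_diffvae",
    "predict_links",
]


@dataclass
class CellGraph:
    """Symmetric binary adjacency over cells, stored without self-loops."""

    A: np.ndarray
    cell_ids: list[str] | None = None
    self_loop_state: str = "without"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:05d}" for i in range(self.A.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.A.shape[0]

    def edge_list(self) -> np.ndarray:
        """Undirected edges as (i, j) pairs with i < j."""
        iu, ju = np.triu_indices(self.n_cells, k=1)
        mask = self.A[iu, ju] > 0
        return np.column_stack([iu[mask], ju[mask]])

    def with_self_loops(self) -> np.ndarray:
        out = self.A.astype(np.float64).copy()
        np.fill_diagonal(out, 1.0)
        return out


@dataclass
class GraphDiffVAEConfig:
    """Published defaults: 512 hidden features, M = 50 latent features,
    learning rate 1e-4, 200 epochs."""

    hidden_features: int = 512
    latent_features: int = 50
    learning_rate: float = 1e-4
    epochs: int = 200
    seed: int = 0
    edge_pos_weight: float | None = None  # None = #non-edges / #edges

    def __post_init__(self) -> None:
        if min(self.hidden_features, self.latent_features) <= 0 or self.epochs < 0:
            raise ValueError("sizes must be positive and epochs >= 0")


@dataclass
class PredictedGraph:
    """Model output: dense edge probabilities and the latent node features."""

    A_hat: np.ndarray
    Z: np.ndarray
    Z_prime: np.ndarray
    Z_star: np.ndarray
    cell_ids: list[str] | None = None
    mu: np.ndarray | None = field(default=None, repr=False)
    log_var: np.ndarray | None = field(default=None, repr=False)


def correlation_graph(expr) -> CellGraph:
    """Initial cell graph: each cell joined to its most positively
    Pearson-correlated cell.

    The union of the per-cell argmax picks is symmetrised into an undirected
    binary adjacency (ties resolve to the lowest index). Cells with no
    positive correlation to any other cell — including zero-variance cells,
    whose correlations are undefined — stay isolated, with a warning.
    """
    from .preprocess import ExpressionMatrix

    if isinstance(expr, ExpressionMatrix):
        x, cell_ids = expr.values, list(expr.cell_ids)
    else:
        x, cell_ids = np.asarray(expr, dtype=np.float64), None
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    var = x.var(axis=1)
    zero_var = var == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance cell(s): correlation undefined, left isolated",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[~np.isfinite(corr)] = -np.inf
    np.fill_diagonal(corr, -np.inf)
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        if zero_var[i]:
            continue
        j = int(np.argmax(corr[i]))  # ties -> lowest index
        if corr[i, j] > 0:
            adj[i, j] = 1
    adj = np.maximum(adj, adj.T)
    isolated = int((adj.sum(axis=1) == 0).sum())
    if isolated:
        warnings.warn(f"{isolated} cell(s) have no positive correlation and stay isolated",
                      stacklevel=2)
    return CellGraph(A=adj, cell_ids=cell_ids)


def normalize_adjacency(graph: CellGraph | np.ndarray) -> np.ndarray:
    """Symmetric GCN normalisation D^-1/2 (A + I) D^-1/2.

    Self-loops are added before computing degrees, so every degree is
    positive.
    """
    a = graph.with_self_loops() if isinstance(graph, CellGraph) else np.asarray(graph, dtype=np.float64)
    if isinstance(graph, np.ndarray):
        a = a.copy()
        np.fill_diagonal(a, 1.0)
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(a_norm: np.ndarray, x: np.ndarray, w: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One graph convolution: activation(A_norm @ X @ W), no bias."""
    out = a_norm @ x @ w
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "linear":
        return out
    raise ValueError(f"unknown activation: {activation!r}")


class _GCNLayer:
    """GCN layer with cached forward state for the manual backward pass."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, relu: bool) -> None:
        self.W = Parameter(glorot_uniform(rng, n_in, n_out))
        self.relu = relu

    def forward(self, a_norm: np.ndarray, x: np.ndarray, train: bool = True) -> np.ndarray:
        ax = a_norm @ x
        pre = ax @ self.W.value
        out = np.maximum(pre, 0.0) if self.relu else pre
        if train:
            self._cache = (a_norm, ax, pre)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        a_norm, ax, pre = self._cache
        if self.relu:
            g = g * (pre > 0)
        self.W.grad += ax.T @ g
        # a_norm is symmetric, so A^T (g W^T) = A (g W^T)
        return a_norm @ (g @ self.W.value.T)


class GraphDiffVAEModel:
    """Weights of the graph VAE (encoder GCN + Graphite-style decoder)."""

    def __init__(self, n_features: int, config: GraphDiffVAEConfig) -> None:
        self.config = config
        self.n_features = n_features
        h, m = config.hidden_features, config.latent_features
        rng = np.random.default_rng(config.seed)
        self.enc_hidden = _GCNLayer(rng, n_features, h, relu=True)
        self.enc_mu = _GCNLayer(rng, h, m, relu=False)
        self.enc_logvar = _GCNLayer(rng, h, m, relu=False)
        self.dec_hidden = _GCNLayer(rng, m + n_features, h, relu=True)
        self.dec_out = _GCNLayer(rng, h, m, relu=True)

    def params(self) -> list[Parameter]:
        return [
            l.W
            for l in (self.enc_hidden, self.enc_mu, self.enc_logvar, self.dec_hidden, self.dec_out)
        ]

    def encode(self, a_norm: np.ndarray, x: np.ndarray, train: bool = False):
        h = self.enc_hidden.forward(a_norm, x, train=train)
        mu = self.enc_mu.forward(a_norm, h, train=train)
        log_var = self.enc_logvar.forward(a_norm, h, train=train)
        return mu, log_var

    def decode(self, a_norm: np.ndarray, x: np.ndarray, z: np.ndarray, train: bool = False):
        zx = np.concatenate([z, x], axis=1)
        h = self.dec_hidden.forward(a_norm, zx, train=train)
        z_prime = self.dec_out.forward(a_norm, h, train=train)
        z_star = 0.5 * (z_prime + z)
        a_hat = sigmoid(z_star @ z_star.T)
        return a_hat, z_prime, z_star


def graph_encode(graph: CellGraph, x: np.ndarray, model: GraphDiffVAEModel):
    """Per-node Gaussian posterior (mu, log_var), each N x M."""
    a_norm = normalize_adjacency(graph)
    return model.encode(a_norm, np.asarray(x, dtype=np.float64))


def graph_decode(graph: CellGraph, x: np.ndarray, z: np.ndarray, model: GraphDiffVAEModel) -> PredictedGraph:
    """Decode latent node features into a dense symmetric edge-probability
    matrix A_hat = sigmoid(Z* Z*^T), Z* = (Z' + Z) / 2."""
    a_norm = normalize_adjacency(graph)
    a_hat, z_prime, z_star = model.decode(a_norm, np.asarray(x, dtype=np.float64),
                                          np.asarray(z, dtype=np.float64))
    return PredictedGraph(A_hat=a_hat, Z=np.asarray(z, dtype=np.float64),
                          Z_prime=z_prime, Z_star=z_star, cell_ids=graph.cell_ids)


def _weighted_bce(a_target: np.ndarray, a_hat: np.ndarray, pos_weight: float) -> float:
    eps = 1e-7
    ah = np.clip(a_hat, eps, 1 - eps)
    ll = pos_weight * a_target * np.log(ah) + (1.0 - a_target) * np.log(1.0 - ah)
    return float(-ll.sum() / a_target.shape[0])  # averaged per node


def graphvae_loss(a_target: np.ndarray, a_hat: np.ndarray, mu: np.ndarray,
                  log_var: np.ndarray, edge_pos_weight: float = 1.0) -> float:
    """Edge-weighted Bernoulli NLL of A under A_hat plus per-node Gaussian KL,
    both averaged per node."""
    n = a_target.shape[0]
    kl = 0.5 * (mu**2 + np.exp(log_var) - 1.0 - log_var).sum() / n
    return _weighted_bce(np.asarray(a_target, dtype=np.float64), a_hat, edge_pos_weight) + float(kl)


def train_graph_diffvae(
    expr, graph: CellGraph, config: GraphDiffVAEConfig
) -> tuple[PredictedGraph, GraphDiffVAEModel, list[float]]:
    """Full-graph Adam optimisation of the graph VAE objective.

    The reconstruction target is the self-loop-augmented adjacency (the same
    matrix the propagation rule uses); one reparameterised sample of Z is
    drawn per epoch. Returns the final PredictedGraph (from the posterior
    mean), the model and the loss history. Seeded and bit-reproducible.
    """
    from .preprocess import ExpressionMatrix

    x = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=np.float64)
    if x.shape[0] != graph.n_cells:
        raise ValueError("graph and expression matrix disagree on the number of cells")
    n = graph.n_cells
    a_target = graph.with_self_loops()
    a_norm = normalize_adjacency(graph)
    model = GraphDiffVAEModel(x.shape[1], config)
    pos_weight = config.edge_pos_weight
    if pos_weight is None:
        n_pos = a_target.sum()
        pos_weight = float((a_target.size - n_pos) / n_pos)
    history: list[float] = []
    if config.epochs > 0:
        rng = np.random.default_rng(config.seed + 1)
        opt = Adam(model.params(), lr=config.learning_rate)
        m = config.latent_features
        for epoch in range(config.epochs):
            opt.zero_grad()
            mu, log_var = model.encode(a_norm, x, train=True)
            eps = rng.standard_normal(mu.shape)
            sig = np.exp(0.5 * log_var)
            z = mu + eps * sig
            a_hat, z_prime, z_star = model.decode(a_norm, x, z, train=True)
            loss = graphvae_loss(a_target, a_hat, mu, log_var, pos_weight)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            # d(BCE)/d(score matrix S), S = Z* Z*^T
            g_s = (-pos_weight * a_target * (1.0 - a_hat) + (1.0 - a_target) * a_hat) / n
            g_zstar = (g_s + g_s.T) @ z_star
            g_zprime = 0.5 * g_zstar
            g_zx = model.dec_hidden.backward(model.dec_out.backward(g_zprime))
            g_z = g_zx[:, :m] + 0.5 * g_zstar
            g_mu = g_z + mu / n
            g_logvar = g_z * eps * sig * 0.5 + 0.5 * (np.exp(log_var) - 1.0) / n
            g_h = model.enc_mu.backward(g_mu) + model.enc_logvar.backward(g_logvar)
            model.enc_hidden.backward(g_h)
            opt.step()
            history.append(loss)
            logger.info("graphvae epoch %d loss %.6f", epoch, loss)
    mu, log_var = model.encode(a_norm, x, train=False)
    predicted = graph_decode(graph, x, mu, model)
    predicted.mu, predicted.log_var = mu, log_var
    return predicted, model, history


def predict_links(
    predicted: PredictedGraph | np.ndarray,
    input_graph: CellGraph | None = None,
    threshold: float = 0.5,
    top_q: int | None = None,
):
    """Call edges from the dense probability matrix.

    Returns (novel, known): arrays of (i, j, score) rows with i < j, where
    ``known`` are input-graph edges and ``novel`` the remaining pairs passing
    the rule — score >= threshold, or (if ``top_q`` is given) the q
    highest-scoring non-input pairs.
    """
    a_hat = predicted.A_hat if isinstance(predicted, PredictedGraph) else np.asarray(predicted)
    n = a_hat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    scores = a_hat[iu, ju]
    is_input = (
        input_graph.A[iu, ju] > 0 if input_graph is not None else np.zeros(len(iu), dtype=bool)
    )
    known = np.column_stack([iu[is_input], ju[is_input], scores[is_input]])
    cand_i, cand_j, cand_s = iu[~is_input], ju[~is_input], scores[~is_input]
    if top_q is not None:
        order = np.lexsort((cand_i, cand_j, -cand_s))[:top_q]
        sel = np.zeros(len(cand_s), dtype=bool)
        sel[order] = True
    else:
        sel = cand_s >= threshold
    novel = np.column_stack([cand_i[sel], cand_j[sel], cand_s[sel]])
    return novel, known


def write_graph(graph: CellGraph, path) -> None:
    """Two-column TSV edge list of cell ids."""
    ids = graph.cell_ids
    with open(path, "w") as fh:
        for i, j in graph.edge_list():
            fh.write(f"{ids[i]}\t{ids[j]}\n")


def read_graph(path, cell_ids: list[str]) -> CellGraph:
    """Read a two-column TSV edge list against a known cell-id ordering."""
    index = {c: i for i, c in enumerate(cell_ids)}
    n = len(cell_ids)
    adj = np.zeros((n, n), dtype=np.int8)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b = line.split("\t")[:2]
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = 1
    np.fill_diagonal(adj, 0)
    return CellGraph(A=adj, cell_ids=list(cell_ids))
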