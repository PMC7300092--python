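"""Cell-type identification from the latent space and decoder weights.

The pipeline: embed cells (latent means, optionally t-SNE to 2-D), cluster
(k-means or DBSCAN), find for each cluster the latent dimensions whose
"extreme cells" (at least one standard deviation from the dimension mean)
concentrate in that cluster, then read cluster marker genes off the decoder's
composed weight matrix omega = W0 @ W1 @ W2 (the linearisation of the
decoder, ignoring biases and activations). Clusterings are scored against
reference labels with the adjusted Rand index, and a benchmark protocol
repeats embedding + clustering to produce mean-ARI tables across models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffvae import DiffVAEModel, LatentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "DimensionRelevance",
    "GeneWeightMatrix",
    "tsne_embed",
    "cluster",
    "extreme_cells",
    "dimension_relevance",
    "gene_weights",
    "high_weight_genes",
    "cluster_marker_genes",
    "adjusted_rand_index",
    "benchmark",
]


@dataclass
class ClusterAssignment:
    """Cluster labels per cell; -1 marks density-clustering noise."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    embedding_used: str = "latent"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def cluster_ids(self) -> np.ndarray:
        """Non-noise cluster labels, ascending."""
        ids = np.unique(self.labels)
        return ids[ids != -1]


@dataclass
class DimensionRelevance:
    """Percentage composition of each dimension's extreme-cell set by cluster.

    ``percentages[(cluster, dim)]`` is the share (0-100) of the extreme set
    D_dim belonging to ``cluster``; ``top_dims[cluster]`` ranks dimensions by
    that share (descending, ties by dimension index) and keeps ``top_n``.
    """

    percentages: dict
    extreme_sets: dict
    top_dims: dict
    degenerate_dims: list = field(default_factory=list)


@dataclass
class GeneWeightMatrix:
    """The decoder's composed gene-weight matrix omega (m x genes)."""

    omega: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=np.float64)
        if self.gene_names is None:
            self.gene_names = [f"g{j:04d}" for j in range(self.omega.shape[1])]
        if len(self.gene_names) != self.omega.shape[1]:
            raise ValueError("gene_names length must equal omega's column count")


def tsne_embed(latent, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE of the latent means (established algorithm, seeded)."""
    from sklearn.manifold import TSNE

    z = latent.z_means if isinstance(latent, LatentMatrix) else np.asarray(latent, dtype=np.float64)
    if z.shape[0] <= 3 * perplexity:
        raise ValueError(f"need N > 3 * perplexity (N={z.shape[0]}, perplexity={perplexity})")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(z)


def cluster(embedding: np.ndarray, method: str = "kmeans", params: dict | None = None,
            embedding_used: str = "latent") -> ClusterAssignment:
    """Cluster an embedding with k-means or DBSCAN."""
    from sklearn.cluster import DBSCAN, KMeans

    params = dict(params or {})
    x = np.asarray(embedding, dtype=np.float64)
    if method == "kmeans":
        if "n_clusters" not in params:
            raise ValueError("kmeans requires params['n_clusters']")
        km = KMeans(
            n_clusters=int(params["n_clusters"]),
            n_init=int(params.get("n_init", 10)),
            random_state=int(params.get("seed", 0)),
        )
        labels = km.fit_predict(x)
    elif method == "dbscan":
        db = DBSCAN(eps=float(params.get("eps", 0.5)), min_samples=int(params.get("min_samples", 5)))
        labels = db.fit_predict(x)
        if (labels == -1).all():
            warnings.warn("DBSCAN labelled every cell as noise", stacklevel=2)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    return ClusterAssignment(labels=labels, method=method, params=params, embedding_used=embedding_used)


def extreme_cells(z_k: np.ndarray, mu_k: float | None = None, sigma_k: float | None = None) -> np.ndarray:
    """Cells at least one standard deviation from the dimension mean.

    D_k = { i : z_k[i] >= mu_k + sigma_k  or  z_k[i] <= mu_k - sigma_k },
    boundaries inclusive; sigma uses the population convention (divide by N).
    A degenerate dimension (sigma_k == 0) returns the empty set — the literal
    rule would select every cell, which carries no information.
    """
    z = np.asarray(z_k, dtype=np.float64)
    if mu_k is None:
        mu_k = float(z.mean())
    if sigma_k is None:
        sigma_k = float(z.std())  # population sd
    if sigma_k == 0.0:
        logger.warning("degenerate latent dimension (sigma = 0): empty extreme set")
        return np.array([], dtype=int)
    return np.flatnonzero((z >= mu_k + sigma_k) | (z <= mu_k - sigma_k))


def dimension_relevance(latent: LatentMatrix, clusters: ClusterAssignment, top_n: int = 10) -> DimensionRelevance:
    """Rank latent dimensions by how much their extreme set concentrates in
    each cluster.

    For each dimension k the extreme set D_k is split across all cluster
    labels (noise included, so the shares sum to 100 for non-empty D_k);
    for each non-noise cluster C the dimensions are ranked by the percentage
    of D_k belonging to C (descending, ties by dimension index).
    """
    labels = clusters.labels
    if len(labels) != latent.n_cells:
        raise ValueError("cluster labels and latent matrix disagree on N")
    cluster_ids = clusters.cluster_ids
    if cluster_ids.size == 0:
        raise ValueError("need at least one non-noise cluster")
    all_ids = np.unique(labels)
    percentages: dict = {}
    extreme_sets: dict = {}
    degenerate: list[int] = []
    for k in range(latent.m):
        d_k = extreme_cells(latent.z_means[:, k], latent.dim_means[k], latent.dim_sds[k])
        extreme_sets[k] = d_k
        if d_k.size == 0:
            if latent.dim_sds[k] == 0.0:
                degenerate.append(k)
            for c in all_ids:
                percentages[(c, k)] = 0.0
            continue
        sub = labels[d_k]
        for c in all_ids:
            percentages[(c, k)] = 100.0 * float((sub == c).sum()) / d_k.size
    top_dims = {}
    for c in cluster_ids:
        scores = np.array([percentages[(c, k)] for k in range(latent.m)])
        order = np.lexsort((np.arange(latent.m), -scores))  # desc score, ties by index
        top_dims[c] = list(order[:top_n])
    return DimensionRelevance(
        percentages=percentages,
        extreme_sets=extreme_sets,
        top_dims=top_dims,
        degenerate_dims=degenerate,
    )


def gene_weights(decoder, gene_names: list[str] | None = None) -> GeneWeightMatrix:
    """omega = W0 @ W1 @ W2, the decoder's composed weight matrix.

    ``decoder`` is either a :class:`DiffVAEModel` or a (W0, W1, W2) triple
    with shapes (m, h1), (h1, h2), (h2, genes). Biases and activations are
    excluded: omega[i, j] is the weight of latent dimension i on gene j under
    the linearised decoder.
    """
    if isinstance(decoder, DiffVAEModel):
        w0, w1, w2 = decoder.decoder_weight_matrices
    else:
        w0, w1, w2 = (np.asarray(w, dtype=np.float64) for w in decoder)
    if w0.shape[1] != w1.shape[0] or w1.shape[1] != w2.shape[0]:
        raise ValueError(f"non-conformable decoder shapes {w0.shape}, {w1.shape}, {w2.shape}")
    return GeneWeightMatrix(omega=w0 @ w1 @ w2, gene_names=gene_names)


def high_weight_genes(omega: GeneWeightMatrix, dims: list[int], top_g: int = 3):
    """Top genes per latent dimension by |omega|, plus the cross-dimension sets.

    Genes are sorted by descending absolute weight (ties by gene index).
    Returns (per_dim, common, counts): per-dimension ranked gene-name lists,
    the genes common to every selected dimension's top list, and a Counter of
    how many selected dimensions each gene appears in.
    """
    from collections import Counter

    m, k = omega.omega.shape
    bad = [d for d in dims if not 0 <= d < m]
    if bad:
        raise ValueError(f"dimensions {bad} outside omega's {m} rows")
    if top_g > k:
        warnings.warn(f"top_g={top_g} exceeds {k} genes; clipping", stacklevel=2)
        top_g = k
    per_dim: dict[int, list[str]] = {}
    for d in dims:
        row = np.abs(omega.omega[d])
        order = np.lexsort((np.arange(k), -row))
        per_dim[d] = [omega.gene_names[j] for j in order[:top_g]]
    counts = Counter(g for genes in per_dim.values() for g in genes)
    common = set.intersection(*(set(v) for v in per_dim.values())) if per_dim else set()
    return per_dim, common, counts


def cluster_marker_genes(omega: GeneWeightMatrix, dims: list[int], top_g: int = 10) -> list[str]:
    """Marker genes for a cluster: top genes by |omega| pooled over the
    cluster's relevant latent dimensions.

    Ranks genes by sum_{k in dims} |omega[k, j]| (descending, ties by gene
    index) and returns the top ``top_g`` names. Pooling the evidence across
    the selected dimensions is robust to any single weakly-informative
    dimension, whose weight row is dominated by initialisation noise.
    """
    m, k = omega.omega.shape
    bad = [d for d in dims if not 0 <= d < m]
    if bad:
        raise ValueError(f"dimensions {bad} outside omega's {m} rows")
    score = np.abs(omega.omega[list(dims)]).sum(axis=0)
    order = np.lexsort((np.arange(k), -score))
    return [omega.gene_names[j] for j in order[: min(top_g, k)]]


def adjusted_rand_index(labels_a, labels_b, noise_policy: str = "own_cluster") -> float:
    """Chance-corrected agreement between two partitions, in [-1, 1].

    ``noise_policy="own_cluster"`` keeps the density-clustering noise label
    (-1) as one extra cluster; ``"drop"`` removes cells labelled noise in
    either partition before scoring.
    """
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if noise_policy == "drop":
        keep = (a != -1) & (b != -1)
        a, b = a[keep], b[keep]
    elif noise_policy != "own_cluster":
        raise ValueError("noise_policy must be 'own_cluster' or 'drop'")
    return float(adjusted_rand_score(a, b))


def _embed_for_model(expr, model_kind: str, m: int, epochs: int, seed: int):
    """Train one embedding model and return its LatentMatrix."""
    from . import baselines as bl
    from . import diffvae as dv

    if model_kind == "diffvae":
        cfg = dv.DiffVAEConfig(m=m, epochs=epochs, seed=seed)
        model, _ = dv.train_diffvae(expr, cfg)
        return dv.get_latent(model, expr)
    if model_kind == "vae":
        _, lat, _ = bl.train_vae(expr, bl.BaselineConfig(kind="vae", m=m, epochs=epochs, seed=seed))
        return lat
    if model_kind == "ae":
        _, lat, _ = bl.train_ae(expr, bl.BaselineConfig(kind="ae", m=m, epochs=epochs, seed=seed))
        return lat
    if model_kind == "pca":
        return bl.pca_embed(expr, m, seed=seed)
    raise ValueError(f"unknown model kind: {model_kind!r}")


def benchmark(
    expr,
    true_labels,
    models=("diffvae", "vae", "ae", "pca"),
    m_values=(20, 50, 100),
    clusterers=("kmeans", "dbscan"),
    embeddings=("latent", "tsne"),
    repeats: int = 50,
    epochs: int = 100,
    seed: int = 0,
    perplexity: float = 30.0,
    dbscan_params: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-ARI comparison of embedding models under repeated clustering.

    For every (model, m, clusterer, embedding) cell the clustering — and the
    t-SNE embedding, where applicable — is recomputed ``repeats`` times with
    fresh seeds and scored against ``true_labels``. Returns the long-format
    per-repeat table and the pivoted mean-ARI table.
    """
    true_labels = np.asarray(true_labels)
    n_clusters = len(np.unique(true_labels))
    rows = []
    for model_kind in models:
        for m in m_values:
            lat = _embed_for_model(expr, model_kind, m, epochs, seed)
            for embedding_kind in embeddings:
                for clusterer in clusterers:
                    for rep in range(repeats):
                        rep_seed = seed + 1000 * rep + 7
                        if embedding_kind == "tsne":
                            emb = tsne_embed(lat, perplexity=perplexity, seed=rep_seed)
                        else:
                            emb = lat.z_means
                        params = (
                            {"n_clusters": n_clusters, "seed": rep_seed}
                            if clusterer == "kmeans"
                            else dict(dbscan_params or {})
                        )
                        assign = cluster(emb, method=clusterer, params=params,
                                         embedding_used=embedding_kind)
                        ari = adjusted_rand_index(true_labels, assign.labels)
                        rows.append(
                            {
                                "model": model_kind,
                                "m": m,
                                "clusterer": clusterer,
                                "embedding": embedding_kind,
                                "repeat": rep,
                                "ari": ari,
                            }
                        )
    long = pd.DataFrame(rows)
    mean_table = long.pivot_table(
        index=["clusterer", "m"], columns=["embedding", "model"], values="ari", aggfunc="mean"
    )
    return long, mean_table
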