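"""Synthetic single-cell expression data with planted cluster structure.

Generates nonnegative, log-scale expression matrices with a configurable
number of mature cell clusters, each carrying a block of planted marker genes
(mean shifted up inside the cluster), plus an optional "progenitor"
population whose centroid is the average of the mature centroids — emulating
a population of stem/progenitor cells sitting between differentiated cell
types. A ground-truth within-cluster cell graph can be derived from a
generated dataset to exercise the graph autoencoder.

The generator works on the log-normalised scale the downstream models
consume; it does not simulate count-level phenomena (dropout, library size,
negative-binomial noise) or batch effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_expression",
    "generate_labeled_graph",
]


@dataclass
class SyntheticSpec:
    """Configuration for the synthetic expression generator.

    Parameters
    ----------
    n_cells, n_genes, n_clusters
        Dataset dimensions; ``n_clusters`` counts the mature clusters only
        (the progenitor population, if requested, is an extra cluster).
    markers_per_cluster
        Number of marker genes planted per mature cluster.
    marker_effect
        Log-scale mean shift of a marker gene inside its own cluster.
    base_scale
        Baseline log-scale mean shared by all genes outside marker blocks.
    noise_sd
        Standard deviation of the additive Gaussian noise (truncated at 0).
    progenitor_fraction
        Fraction of cells assigned to the progenitor population, whose
        centroid is the average of the mature cluster centroids.
    seed
        Seed of the single RNG stream used for the whole draw.
    """

    n_cells: int = 500
    n_genes: int = 200
    n_clusters: int = 4
    markers_per_cluster: int = 10
    marker_effect: float = 3.0
    base_scale: float = 1.0
    noise_sd: float = 0.5
    progenitor_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_clusters, self.markers_per_cluster) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_clusters * self.markers_per_cluster > self.n_genes:
            raise ValueError("n_clusters * markers_per_cluster must be <= n_genes")
        if self.n_cells < self.n_clusters:
            raise ValueError("need at least one cell per cluster")
        if not 0.0 <= self.progenitor_fraction <= 1.0:
            raise ValueError("progenitor_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.marker_effect <= 0 or self.base_scale < 0:
            raise ValueError("noise_sd >= 0, marker_effect > 0, base_scale >= 0 required")


@dataclass
class SyntheticDataset:
    """A generated expression matrix with its ground truth."""

    expression: ExpressionMatrix
    labels: np.ndarray
    marker_map: dict[int, list[str]]
    progenitor_label: int | None = None
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)

    @property
    def mature_labels(self) -> np.ndarray:
        """Boolean mask selecting cells in mature (non-progenitor) clusters."""
        if self.progenitor_label is None:
            return np.ones(len(self.labels), dtype=bool)
        return self.labels != self.progenitor_label


def _cluster_sizes(n_cells: int, n_mature: int, progenitor_fraction: float) -> list[int]:
    n_prog = int(round(progenitor_fraction * n_cells)) if progenitor_fraction > 0 else 0
    n_rest = n_cells - n_prog
    base, extra = divmod(n_rest, n_mature)
    sizes = [base + (1 if c < extra else 0) for c in range(n_mature)]
    if n_prog > 0:
        sizes.append(n_prog)
    return sizes


def generate_expression(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a synthetic log-scale expression matrix with planted markers.

    Cluster labels are assigned in contiguous blocks of cell index, so the
    label of a cell is a deterministic function of its index. Marker gene
    ``j`` of mature cluster ``c`` has mean ``base_scale + marker_effect``
    inside ``c`` and ``base_scale`` elsewhere; all non-marker genes share the
    cluster-independent mean ``base_scale``. Gaussian noise with standard
    deviation ``noise_sd`` is added and values are truncated at zero. The
    progenitor cluster's centroid is the average of the mature centroids.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_mature = spec.n_clusters
    sizes = _cluster_sizes(spec.n_cells, n_mature, spec.progenitor_fraction)
    has_prog = len(sizes) > n_mature
    labels = np.repeat(np.arange(len(sizes)), sizes)

    # mature centroids: baseline everywhere, markers lifted inside the cluster
    centroids = np.full((len(sizes), spec.n_genes), float(spec.base_scale))
    marker_map: dict[int, list[str]] = {}
    gene_names = [f"g{j:04d}" for j in range(spec.n_genes)]
    for c in range(n_mature):
        start = c * spec.markers_per_cluster
        idx = np.arange(start, start + spec.markers_per_cluster)
        centroids[c, idx] += spec.marker_effect
        marker_map[c] = [gene_names[j] for j in idx]
    if has_prog:
        centroids[n_mature] = centroids[:n_mature].mean(axis=0)

    values = centroids[labels] + rng.normal(0.0, spec.noise_sd, size=(spec.n_cells, spec.n_genes))
    np.maximum(values, 0.0, out=values)

    cell_ids = [f"cell{i:05d}" for i in range(spec.n_cells)]
    expr = ExpressionMatrix(
        values=values,
        gene_names=gene_names,
        cell_ids=cell_ids,
        labels=labels.copy(),
        scale_state="log_normalized",
    )
    return SyntheticDataset(
        expression=expr,
        labels=labels,
        marker_map=marker_map,
        progenitor_label=n_mature if has_prog else None,
        spec=spec,
    )


def generate_labeled_graph(
    dataset: SyntheticDataset, k: int = 3, seed: int | None = None
):
    """Ground-truth cell graph linking each cell to same-cluster cells only.

    Each cell receives ``k`` random within-cluster neighbours (fewer if the
    cluster is smaller); the union of the directed picks is symmetrised.
    Cells in singleton clusters stay isolated (with a warning). Returns a
    :class:`scdiffvae.graphvae.CellGraph` without stored self-loops.
    """
    from .graphvae import CellGraph

    labels = np.asarray(dataset.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters to build a labeled graph")
    n = len(labels)
    rng = np.random.default_rng(dataset.spec.seed if seed is None else seed)
    adj = np.zeros((n, n), dtype=np.int8)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 1:
            warnings.warn(f"cluster {lab} has a single cell; it gets no edge", stacklevel=2)
            continue
        for i in members:
            others = members[members != i]
            picks = rng.choice(others, size=min(k, others.size), replace=False)
            adj[i, picks] = 1
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0)
    return CellGraph(A=adj, cell_ids=list(dataset.expression.cell_ids))


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write expression (CSV), labels (CSV) and marker map (CSV) to a directory."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = dataset.expression
    paths = {}
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_names)
    paths["expression"] = str(out / "expression.csv")
    df.to_csv(paths["expression"], index_label="cell_id")
    lab = pd.DataFrame({"cell_id": expr.cell_ids, "label": dataset.labels})
    paths["labels"] = str(out / "labels.csv")
    lab.to_csv(paths["labels"], index=False)
    rows = [
        {"cluster": c, "gene": g}
        for c, genes in dataset.marker_map.items()
        for g in genes
    ]
    paths["markers"] = str(out / "markers.csv")
    pd.DataFrame(rows).to_csv(paths["markers"], index=False)
    return paths
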