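"""In-silico cell-state conversion by latent perturbation.

A softmax classifier is trained on the mature cell types; progenitor cells
are then pushed toward a chosen mature type by shifting the latent
dimensions most relevant for that type (from
:func:`scdiffvae.celltype.dimension_relevance`) by ``lambda * sigma_k``,
decoding the shifted code, and asking the classifier what the reconstructed
cell now looks like. Gene-level deltas between the reconstruction and the
original expression rank which genes an in-silico conversion changes, and a
ranked-prefix scan finds the smallest set of genes whose substitution alone
flips the classifier.

The shift direction for each selected dimension points toward the target
cluster's side of the dimension mean (the extreme-cell rule is two-sided, so
a sign rule is needed); it can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diffvae import DiffVAEModel, LatentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierModel",
    "PerturbationSpec",
    "PerturbationResult",
    "train_classifier",
    "shift_directions",
    "perturb_latent",
    "convert_cells",
    "gene_delta",
    "minimal_gene_set",
]


@dataclass
class ClassifierModel:
    """A softmax MLP over mature cell classes (256, 512, 256 hidden ReLU
    units; Adam, lr 0.001, batch 128, 300 epochs)."""

    clf: object
    classes: np.ndarray
    training_accuracy: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.clf.predict(np.atleast_2d(np.asarray(x, dtype=np.float64)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(np.atleast_2d(np.asarray(x, dtype=np.float64)))


@dataclass
class PerturbationSpec:
    """A (target, dims, lambda) latent shift."""

    target_cluster: int
    dims: list[int]
    lam: float = 1.0
    directions: np.ndarray | None = None  # +1/-1 per dim; None = toward target

    def __post_init__(self) -> None:
        if not self.dims:
            raise ValueError("dims must be non-empty")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class PerturbationResult:
    """Per-cell outcome of a latent perturbation."""

    original_class: np.ndarray
    predicted_class: np.ndarray
    converted: np.ndarray
    z_shifted: np.ndarray
    reconstruction: np.ndarray
    conversion_fraction: float
    spec: PerturbationSpec = field(repr=False, default=None)


def train_classifier(
    x: np.ndarray,
    labels: np.ndarray,
    epochs: int = 300,
    learning_rate: float = 0.001,
    batch_size: int = 128,
    seed: int = 0,
) -> ClassifierModel:
    """Train the mature-cell softmax classifier on full gene expression."""
    from sklearn.neural_network import MLPClassifier

    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("classifier needs at least 2 classes")
    clf = MLPClassifier(
        hidden_layer_sizes=(256, 512, 256),
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate,
        batch_size=min(batch_size, x.shape[0]),
        max_iter=epochs,
        random_state=seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, labels)
    acc = float((clf.predict(x) == labels).mean())
    logger.info("classifier training accuracy: %.4f", acc)
    return ClassifierModel(clf=clf, classes=clf.classes_, training_accuracy=acc)


def shift_directions(latent: LatentMatrix, labels: np.ndarray, target_cluster: int,
                     dims: list[int]) -> np.ndarray:
    """+1/-1 per dimension: the side of the dimension mean on which the
    target cluster's cells sit (ties resolve to +1)."""
    labels = np.asarray(labels)
    mask = labels == target_cluster
    if not mask.any():
        raise ValueError(f"no cells in target cluster {target_cluster}")
    dirs = np.ones(len(dims))
    for i, d in enumerate(dims):
        delta = latent.z_means[mask, d].mean() - latent.dim_means[d]
        dirs[i] = -1.0 if delta < 0 else 1.0
    return dirs


def perturb_latent(z: np.ndarray, spec: PerturbationSpec, sigma_dims: np.ndarray,
                   directions: np.ndarray | None = None) -> np.ndarray:
    """Shift selected coordinates: z'_j = z_j + direction_j * lambda * sigma_j.

    Works on a single latent vector or a matrix of row vectors; coordinates
    outside ``spec.dims`` are untouched.
    """
    z = np.asarray(z, dtype=np.float64)
    out = z.copy()
    dirs = directions if directions is not None else spec.directions
    if dirs is None:
        dirs = np.ones(len(spec.dims))
    sigma_dims = np.asarray(sigma_dims, dtype=np.float64)
    if sigma_dims.shape[0] != len(spec.dims):
        raise ValueError("need one sigma per shifted dimension")
    shift = np.asarray(dirs) * spec.lam * sigma_dims
    if out.ndim == 1:
        out[list(spec.dims)] += shift
    else:
        out[:, list(spec.dims)] += shift
    return out


def convert_cells(
    model: DiffVAEModel,
    classifier: ClassifierModel,
    source_cells: np.ndarray,
    spec: PerturbationSpec,
    latent: LatentMatrix,
) -> PerturbationResult:
    """Encode, shift, decode and re-classify a set of source cells.

    ``latent`` supplies the dataset-level per-dimension statistics (sigma_k
    and means) that scale the shift. The conversion fraction is the share of
    source cells whose reconstruction the classifier assigns to the target.
    """
    x = np.atleast_2d(np.asarray(source_cells, dtype=np.float64))
    mu, _ = model.encode(x)
    sigma_dims = latent.dim_sds[list(spec.dims)]
    z_shifted = perturb_latent(mu, spec, sigma_dims)
    y = model.decode(z_shifted)
    original = classifier.predict(x)
    predicted = classifier.predict(y)
    converted = predicted == spec.target_cluster
    return PerturbationResult(
        original_class=original,
        predicted_class=predicted,
        converted=converted,
        z_shifted=z_shifted,
        reconstruction=y,
        conversion_fraction=float(converted.mean()),
        spec=spec,
    )


def gene_delta(x: np.ndarray, y: np.ndarray):
    """Per-gene change delta = y - x, ranked by |delta| (ties by gene index).

    Returns (delta, order) where ``order`` indexes genes from most to least
    changed; delta's sign distinguishes up- from down-regulation.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must share the gene space")
    delta = y - x
    order = np.lexsort((np.arange(delta.size), -np.abs(delta)))
    return delta, order


def minimal_gene_set(x: np.ndarray, y: np.ndarray, classifier: ClassifierModel, target) -> tuple[int, np.ndarray]:
    """Smallest |delta|-ranked gene prefix whose substitution flips the class.

    Genes are ranked by the magnitude of their change between x and its
    converted reconstruction y; for growing g, a hybrid cell takes its top-g
    genes from y and the rest from x. Returns the first g at which the
    classifier assigns the hybrid to ``target`` (g = 0 if x already is, and
    g <= n_genes always, since the hybrid equals y at g = n_genes).

    Precondition: classifier(y) == target.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if classifier.predict(y[None, :])[0] != target:
        raise ValueError("classifier must assign the converted cell y to the target class")
    _, order = gene_delta(x, y)
    hybrid = x.copy()
    if classifier.predict(hybrid[None, :])[0] == target:
        return 0, order[:0]
    for g in range(1, x.size + 1):
        j = order[g - 1]
        hybrid[j] = y[j]
        if classifier.predict(hybrid[None, :])[0] == target:
            return g, order[:g]
    raise AssertionError("unreachable: hybrid equals y at g = n_genes")
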