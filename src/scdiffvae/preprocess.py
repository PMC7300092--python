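"""Expression-matrix loading and Min-Max normalisation.

The autoencoders model each gene of a cell as a Bernoulli variable, so their
input must live in [0, 1]. Inputs are assumed to be log-normalised expression
(cells x genes); :func:`minmax_scale` rescales each gene across cells to the
unit interval and retains the per-gene parameters for the inverse mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "load_expression", "minmax_scale", "inverse_minmax"]


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values in a known scale state.

    ``scale_state`` is either ``"log_normalized"`` (as loaded) or
    ``"unit_scaled"`` (after per-gene Min-Max scaling, all values in [0, 1]).
    After scaling, ``col_min``/``col_range`` hold the per-gene transform so it
    can be inverted.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None
    scale_state: str = "log_normalized"
    col_min: np.ndarray | None = field(default=None, repr=False)
    col_range: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, k = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_names) != k:
            raise ValueError("gene/cell name lengths do not match the matrix shape")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN entries")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match the number of cells")
        if self.scale_state not in ("log_normalized", "unit_scaled"):
            raise ValueError(f"unknown scale_state: {self.scale_state!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _read_mtx(path: Path, cells_first: bool | None) -> tuple[np.ndarray, list[str], list[str]]:
    from scipy.io import mmread

    mat = mmread(str(path))
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    genes_file = path.parent / "genes.txt"
    cells_file = path.parent / "cells.txt"
    if not genes_file.exists() or not cells_file.exists():
        raise FileNotFoundError("MTX input requires genes.txt and cells.txt sidecar files")
    gene_names = genes_file.read_text().split()
    cell_ids = cells_file.read_text().split()
    n_cells, n_genes = len(cell_ids), len(gene_names)
    if cells_first is None:
        # orientation auto-detect from sidecar lengths
        if mat.shape == (n_cells, n_genes):
            cells_first = True
        elif mat.shape == (n_genes, n_cells):
            cells_first = False
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither ({n_cells}, {n_genes}) nor its transpose"
            )
    if not cells_first:
        mat = mat.T
    if mat.shape != (n_cells, n_genes):
        raise ValueError("MTX shape does not match sidecar files")
    return mat, gene_names, cell_ids


def load_expression(
    path,
    format: str | None = None,
    cells_first: bool | None = None,
    log1p: bool = False,
    labels_path=None,
) -> ExpressionMatrix:
    """Load a cells x genes expression matrix from CSV, TSV or MatrixMarket.

    CSV/TSV layout: header row = gene names, first column = cell ids. MTX
    input expects ``genes.txt`` and ``cells.txt`` sidecars next to the matrix;
    orientation is auto-detected from the sidecar lengths and can be forced
    with ``cells_first``. ``log1p`` applies log(1 + x) for raw-count inputs
    (the default assumes data is already log-normalised).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "mtx":
        values, gene_names, cell_ids = _read_mtx(path, cells_first)
    elif format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        values = df.to_numpy(dtype=np.float64)
        gene_names = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]
        if cells_first is False:
            values = values.T
            gene_names, cell_ids = cell_ids, gene_names
    else:
        raise ValueError(f"unknown format: {format!r}")
    if np.isnan(values).any():
        raise ValueError(f"{path} contains missing values")
    if log1p:
        values = np.log1p(values)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        lab = lab.set_index(lab.columns[0])[lab.columns[1]]
        labels = lab.reindex(cell_ids).to_numpy()
    return ExpressionMatrix(
        values=values,
        gene_names=gene_names,
        cell_ids=cell_ids,
        labels=labels,
        scale_state="log_normalized",
    )


def minmax_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Min-Max scale to [0, 1]: ``(x - min) / (max - min)``.

    Constant genes map to 0 (flagged in the log) so that gene indexing stays
    stable for downstream decoder-weight analysis. The per-gene minima and
    ranges are retained on the returned matrix for :func:`inverse_minmax`.
    """
    if expr.scale_state != "log_normalized":
        raise ValueError("minmax_scale expects a log_normalized matrix")
    col_min = expr.values.min(axis=0)
    col_max = expr.values.max(axis=0)
    col_range = col_max - col_min
    constant = col_range == 0
    if constant.any():
        names = [expr.gene_names[j] for j in np.flatnonzero(constant)[:10]]
        logger.warning(
            "%d constant gene(s) mapped to 0 by Min-Max scaling (e.g. %s)",
            int(constant.sum()),
            ", ".join(names),
        )
    safe_range = np.where(constant, 1.0, col_range)
    scaled = (expr.values - col_min) / safe_range
    scaled[:, constant] = 0.0
    return ExpressionMatrix(
        values=scaled,
        gene_names=list(expr.gene_names),
        cell_ids=list(expr.cell_ids),
        labels=None if expr.labels is None else np.asarray(expr.labels).copy(),
        scale_state="unit_scaled",
        col_min=col_min,
        col_range=col_range,
    )


def inverse_minmax(expr: ExpressionMatrix) -> np.ndarray:
    """Undo :func:`minmax_scale`; exact for non-constant genes."""
    if expr.scale_state != "unit_scaled" or expr.col_min is None:
        raise ValueError("inverse_minmax requires a matrix produced by minmax_scale")
    return expr.values * expr.col_range + expr.col_min


def write_expression(expr: ExpressionMatrix, path, format: str = "csv") -> None:
    """Write a matrix as CSV/TSV (header = genes, index = cell ids) or MTX."""
    path = Path(path)
    if format in ("csv", "tsv"):
        df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_names)
        df.to_csv(path, sep="," if format == "csv" else "\t", index_label="cell_id")
    elif format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(expr.values))
        (path.parent / "genes.txt").write_text("\n".join(expr.gene_names) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(expr.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")
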