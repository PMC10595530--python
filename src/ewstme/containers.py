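"""In-memory containers for expression matrices.

Matrices are stored genes x cells (features on rows), matching the layout
of Matrix Market exports of plate-based scRNA-seq experiments.  Gene
symbols and cell barcodes are the external identity of rows/columns; all
positional indexing is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    X: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell_id")
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if not self.genes.is_unique:
            raise ValueError("gene symbols are not unique")
        if not self.cells.is_unique:
            raise ValueError("cell ids are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def depth(self) -> np.ndarray:
        """Per-cell library size (column sums)."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with count > 0."""
        return np.asarray((self.X > 0).sum(axis=0)).ravel()

    def subset(self, genes=None, cells=None) -> "CountMatrix":
        gi = slice(None) if genes is None else self.genes.get_indexer(genes)
        ci = slice(None) if cells is None else self.cells.get_indexer(cells)
        if genes is not None and (np.asarray(gi) < 0).any():
            missing = [g for g, i in zip(genes, gi) if i < 0]
            raise KeyError(f"unknown genes: {missing[:5]}")
        if cells is not None and (np.asarray(ci) < 0).any():
            missing = [c for c, i in zip(cells, ci) if i < 0]
            raise KeyError(f"unknown cells: {missing[:5]}")
        X = self.X[gi, :][:, ci]
        return CountMatrix(
            X,
            self.genes if genes is None else self.genes[gi],
            self.cells if cells is None else self.cells[ci],
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


@dataclass
class NormMatrix:
    """Dense genes x cells matrix of normalized expression.

    ``method`` records how the values were produced: ``log1p_cp10k``
    (log of counts-per-10k) or ``pearson_residual`` (analytic Pearson
    residuals of a fixed-dispersion NB model).
    """

    X: np.ndarray
    genes: pd.Index
    cells: pd.Index
    method: str = "log1p_cp10k"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell_id")
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError("matrix shape does not match gene/cell axes")
        if not np.isfinite(self.X).all():
            raise ValueError("normalized matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def gene_values(self, symbols) -> np.ndarray:
        idx = self.genes.get_indexer(symbols)
        if (idx < 0).any():
            missing = [s for s, i in zip(symbols, idx) if i < 0]
            raise KeyError(f"unknown genes: {missing[:5]}")
        return self.X[idx, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.genes, columns=self.cells)
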