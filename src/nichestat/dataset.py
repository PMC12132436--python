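"""Common data carrier for imaging-based spatial transcriptomics.

A :class:`SpatialDataset` couples a per-cell metadata table (coordinates in
micrometres, sample of origin, condition label) with a gene x cell count
matrix from a targeted probe panel, plus an optional log-normalized layer.
All downstream statistics in this package consume this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

METADATA_COLUMNS = ["cell_id", "x_um", "y_um", "sample_id", "condition"]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class SpatialDataset:
    """Cells with spatial coordinates and a gene x cell count matrix.

    Parameters
    ----------
    cells
        One row per cell with columns ``cell_id, x_um, y_um, sample_id,
        condition``. Row order defines cell order in ``counts``.
    genes
        Gene names, in the row order of ``counts``.
    counts
        Sparse (genes x cells) matrix of non-negative integer counts.
    norm
        Optional matching matrix of log-normalized values; ``None`` until
        :func:`nichestat.io_qc.normalize` is applied.
    """

    cells: pd.DataFrame
    genes: list[str]
    counts: sparse.csc_matrix
    norm: sparse.csc_matrix | None = field(default=None)

    def __post_init__(self) -> None:
        self.cells = self.cells.reset_index(drop=True)
        if not sparse.issparse(self.counts):
            self.counts = sparse.csc_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsc()
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.cells.columns]
        if missing:
            raise DatasetError(f"cell table missing columns: {missing}")
        ids = self.cells["cell_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate cell_id values: {dupes[:5]}")
        coords = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            bad = self.cells.loc[~np.isfinite(coords).all(axis=1), "cell_id"]
            raise DatasetError(f"non-finite coordinates for cells: {bad.tolist()[:5]}")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise DatasetError(
                f"counts shape {self.counts.shape} != "
                f"(genes={len(self.genes)}, cells={len(self.cells)})"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise DatasetError("negative values in count matrix")
            if not np.allclose(data, np.round(data)):
                raise DatasetError("non-integer values in count matrix")
        if len(set(self.genes)) != len(self.genes):
            raise DatasetError("duplicate gene names")

    # -- convenience -----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def cell_ids(self) -> pd.Series:
        return self.cells["cell_id"]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def total_counts(self) -> np.ndarray:
        """Per-cell total transcript count."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one transcript."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "SpatialDataset":
        """New dataset restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return SpatialDataset(
            cells=self.cells.loc[mask].reset_index(drop=True),
            genes=list(self.genes),
            counts=self.counts[:, mask],
            norm=None if self.norm is None else self.norm[:, mask],
        )

    def norm_row(self, gene: str) -> np.ndarray:
        if self.norm is None:
            raise DatasetError("dataset has no normalized layer; run normalize() first")
        return np.asarray(self.norm[self.gene_index(gene)].todense()).ravel()

    def counts_row(self, gene: str) -> np.ndarray:
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()
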