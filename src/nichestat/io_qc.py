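"""Flat-file I/O, cell quality control and log-normalization.

Readers accept the two interchange layouts common for imaging-based panels:
a MatrixMarket triplet with ``genes.tsv``/``cells.tsv`` sidecars, or a wide
CSV (genes x cells). QC retains cells with strictly more than ``min_probes``
genes detected and strictly more than ``min_transcripts`` total transcripts;
normalization is library-size scaling over the full probe panel followed by
log1p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dataset import METADATA_COLUMNS, DatasetError, SpatialDataset


class LoadError(ValueError):
    """Raised when flat files cannot be assembled into a valid dataset."""


@dataclass
class QCReport:
    """Outcome of the cell QC filter.

    ``per_cell`` has one row per input cell with its detected-gene count,
    total transcripts and pass/fail flag.
    """

    n_input: int
    n_retained: int
    min_probes: int
    min_transcripts: int
    per_cell: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.per_cell.to_csv(path, sep="\t", index=False)


def read_dataset(
    metadata_path: str | Path,
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> SpatialDataset:
    """Read a spatial dataset from flat files.

    ``matrix_path`` ending in ``.mtx`` is read as MatrixMarket with gene and
    cell sidecars (defaulting to ``genes.tsv``/``cells.tsv`` next to the
    matrix); any other extension is read as wide CSV with gene names in the
    first column and cell ids as header. Matrix columns are aligned to the
    metadata row order by ``cell_id``.
    """
    metadata_path = Path(metadata_path)
    matrix_path = Path(matrix_path)
    meta = pd.read_csv(metadata_path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise LoadError(f"{metadata_path}: missing metadata columns {missing}")
    meta = meta[METADATA_COLUMNS].astype(
        {"cell_id": str, "sample_id": str, "condition": str}
    )

    if matrix_path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else matrix_path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else matrix_path.parent / "cells.tsv"
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
        mat = sparse.csc_matrix(spio.mmread(matrix_path))
    else:
        wide = pd.read_csv(matrix_path, index_col=0)
        genes = [str(g) for g in wide.index]
        cell_ids = [str(c) for c in wide.columns]
        mat = sparse.csc_matrix(wide.to_numpy())

    if mat.shape != (len(genes), len(cell_ids)):
        raise LoadError(
            f"matrix shape {mat.shape} does not match "
            f"{len(genes)} genes x {len(cell_ids)} cells"
        )

    col_of = {cid: j for j, cid in enumerate(cell_ids)}
    if len(col_of) != len(cell_ids):
        raise LoadError("duplicate cell ids in matrix columns")
    absent = [cid for cid in meta["cell_id"] if cid not in col_of]
    if absent:
        raise LoadError(f"cells in metadata but not in matrix: {absent[:5]}")
    extra = set(cell_ids) - set(meta["cell_id"])
    if extra:
        raise LoadError(f"cells in matrix but not in metadata: {sorted(extra)[:5]}")

    order = np.array([col_of[cid] for cid in meta["cell_id"]])
    try:
        return SpatialDataset(cells=meta, genes=genes, counts=mat[:, order])
    except DatasetError as exc:
        raise LoadError(str(exc)) from exc


def write_dataset(ds: SpatialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write metadata CSV + MatrixMarket counts with sidecars; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out_dir / "metadata.csv",
        "matrix": out_dir / "counts.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
    }
    ds.cells[METADATA_COLUMNS].to_csv(paths["metadata"], index=False)
    spio.mmwrite(paths["matrix"], ds.counts.astype(int))
    pd.Series(ds.genes).to_csv(paths["genes"], sep="\t", index=False, header=False)
    ds.cells["cell_id"].to_csv(paths["cells"], sep="\t", index=False, header=False)
    return paths


def qc_filter(
    ds: SpatialDataset,
    min_probes: int = 15,
    min_transcripts: int = 20,
) -> tuple[SpatialDataset, QCReport]:
    """Retain cells with > ``min_probes`` genes detected and > ``min_transcripts``
    transcripts (both inequalities strict)."""
    if min_probes < 0 or min_transcripts < 0:
        raise ValueError("QC thresholds must be non-negative")
    n_probes = ds.genes_detected()
    n_tx = ds.total_counts()
    passed = (n_probes > min_probes) & (n_tx > min_transcripts)
    report = QCReport(
        n_input=ds.n_cells,
        n_retained=int(passed.sum()),
        min_probes=min_probes,
        min_transcripts=min_transcripts,
        per_cell=pd.DataFrame(
            {
                "cell_id": ds.cell_ids,
                "n_probes_detected": n_probes.astype(int),
                "n_transcripts": n_tx.astype(int),
                "passed": passed,
            }
        ),
    )
    if report.n_retained == 0:
        warnings.warn("QC filter removed every cell", stacklevel=2)
    return ds.subset_cells(passed), report


def normalize(ds: SpatialDataset, scale: float = 1e4) -> SpatialDataset:
    """Attach a log-normalized layer: log1p(count * scale / cell total).

    Uses every gene in the probe panel for the cell total. Counts are left
    untouched; the result carries both layers.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = ds.total_counts()
    if np.any(totals == 0):
        raise DatasetError(
            "cells with zero total counts present; apply qc_filter before normalize"
        )
    mat = ds.counts.astype(float).tocsc(copy=True)
    # scale each column by scale/total, then log1p in-place on the sparse data
    inv = scale / totals
    mat = mat @ sparse.diags(inv)
    mat.data = np.log1p(mat.data)
    return SpatialDataset(
        cells=ds.cells.copy(), genes=list(ds.genes), counts=ds.counts, norm=mat.tocsc()
    )
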