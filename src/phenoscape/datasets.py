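"""In-memory containers carried between pipeline stages.

:class:`CellDataset` is the universal carrier: a sparse gene x cell count
matrix with per-cell metadata (embryo, genotype, background strain, trajectory
annotations, QC covariates) and any number of named low-dimensional
embeddings. :class:`CompositionTable` is the embryo x cell-type count matrix
used by composition testing, and :class:`ReferenceAtlas` the staged reference
(embedding plus per-cell developmental time) used for time scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellDataset", "CompositionTable", "ReferenceAtlas", "CELL_COLUMNS"]

#: Canonical per-cell metadata columns; missing optional ones are NaN/"".
CELL_COLUMNS = [
    "cell_id", "embryo_id", "genotype", "background",
    "major_trajectory", "sub_trajectory",
    "umi_count", "gene_count", "mt_frac", "ribo_frac", "doublet_score",
]


@dataclass
class CellDataset:
    """Sparse counts plus aligned cell/gene metadata and named embeddings.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix of shape (n_genes, n_cells).
    cells
        One row per cell; must contain ``cell_id`` (unique) and ``embryo_id``
        (non-empty). Missing optional columns are filled on construction.
    genes
        One row per gene with ``gene_id`` and ``gene_name``.
    embeddings
        Mapping name -> (n_cells, d) float array.
    """

    counts: sp.spmatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        n_genes, n_cells = self.counts.shape
        if len(self.cells) != n_cells:
            raise ValueError(
                f"counts has {n_cells} columns but cells has {len(self.cells)} rows")
        if len(self.genes) != n_genes:
            raise ValueError(
                f"counts has {n_genes} rows but genes has {len(self.genes)} rows")
        self.cells = self.cells.reset_index(drop=True).copy()
        self.genes = self.genes.reset_index(drop=True).copy()
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                self.cells[col] = "" if col in (
                    "genotype", "background", "major_trajectory",
                    "sub_trajectory") else np.nan
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_id values must be unique")
        embryo = self.cells["embryo_id"].astype(str)
        if (embryo == "").any() or embryo.isna().any():
            raise ValueError("embryo_id must be non-empty for every cell")
        for name, emb in list(self.embeddings.items()):
            emb = np.asarray(emb, dtype=float)
            if emb.ndim != 2 or emb.shape[0] != n_cells:
                raise ValueError(
                    f"embedding {name!r} must have one row per cell "
                    f"(got shape {emb.shape}, expected ({n_cells}, d))")
            self.embeddings[name] = emb

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, index) -> "CellDataset":
        """New dataset restricted to the given cell positions or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CellDataset(
            counts=self.counts[:, index],
            cells=self.cells.iloc[index],
            genes=self.genes,
            embeddings={k: v[index] for k, v in self.embeddings.items()},
        )

    def subset_genes(self, index) -> "CellDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CellDataset(
            counts=self.counts[index],
            cells=self.cells,
            genes=self.genes.iloc[index],
            embeddings=dict(self.embeddings),
        )

    def equals(self, other: "CellDataset") -> bool:
        """Structural equality (counts, metadata, embeddings)."""
        if (self.counts.shape != other.counts.shape
                or (self.counts != other.counts).nnz != 0):
            return False
        a, b = self.cells.fillna(""), other.cells.fillna("")
        if not a[sorted(a.columns)].astype(str).equals(b[sorted(b.columns)].astype(str)):
            return False
        if not self.genes.astype(str).equals(other.genes.astype(str)):
            return False
        if set(self.embeddings) != set(other.embeddings):
            return False
        return all(np.allclose(self.embeddings[k], other.embeddings[k],
                               atol=0, rtol=0)
                   for k in self.embeddings)


@dataclass
class CompositionTable:
    """Embryo x cell-type counts with embryo metadata and size factors."""

    counts: pd.DataFrame            # embryos x cell types, non-negative ints
    embryo_meta: pd.DataFrame       # embryo_id, genotype, background
    size_factors: pd.Series         # per embryo, positive

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("composition counts must be non-negative")
        if not self.counts.index.equals(pd.Index(self.embryo_meta["embryo_id"])):
            raise ValueError("counts rows must align with embryo_meta.embryo_id")
        if not np.all(self.size_factors.to_numpy() > 0):
            raise ValueError("size factors must be positive")

    @property
    def n_total(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class ReferenceAtlas:
    """Staged reference: embedding coordinates plus per-cell developmental time."""

    coords: np.ndarray   # (n_cells, d)
    times: np.ndarray    # (n_cells,) developmental days, e.g. 9.5 .. 13.5

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (cells x d)")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per reference cell")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]
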