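"""On-disk layout: Matrix Market counts plus TSV metadata and embeddings.

A dataset directory contains ``matrix.mtx`` (gene x cell, coordinate format,
1-based indices per the Matrix Market standard), ``cells.tsv`` and
``genes.tsv`` (tab-separated with a header row), and an optional
``embeddings/`` directory with one ``<name>.tsv`` per embedding. The layout is
deliberately plain text so fixtures stay human-readable and diff-able.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import CELL_COLUMNS, CellDataset

__all__ = ["read_dataset", "write_dataset", "configure_logging"]

log = logging.getLogger("phenoscape")


def configure_logging(verbose: bool = False) -> None:
    """Timestamped, leveled logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phenoscape")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


def read_dataset(path: str | Path) -> CellDataset:
    """Load a dataset directory written by :func:`write_dataset`.

    Missing optional cell columns are filled with missing markers; a missing
    ``embeddings/`` directory yields an empty embeddings map. Dimension
    mismatches between the matrix and the metadata tables are rejected.
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    try:
        counts = scipy.io.mmread(mtx)
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    counts = sp.csr_matrix(counts)
    if counts.data.size and np.allclose(counts.data, np.round(counts.data)):
        counts = counts.astype(np.int64)

    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype={
        "cell_id": str, "embryo_id": str, "genotype": str, "background": str,
        "major_trajectory": str, "sub_trajectory": str}, keep_default_na=True)
    for col in ("genotype", "background", "major_trajectory", "sub_trajectory"):
        if col in cells.columns:
            cells[col] = cells[col].fillna("")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", dtype=str)

    if len(cells) != counts.shape[1]:
        raise ValueError(
            f"cells.tsv has {len(cells)} rows but matrix.mtx has "
            f"{counts.shape[1]} columns")
    if len(genes) != counts.shape[0]:
        raise ValueError(
            f"genes.tsv has {len(genes)} rows but matrix.mtx has "
            f"{counts.shape[0]} rows")

    embeddings: dict[str, np.ndarray] = {}
    emb_dir = path / "embeddings"
    if emb_dir.is_dir():
        for f in sorted(emb_dir.glob("*.tsv")):
            emb = pd.read_csv(f, sep="\t",
                              float_precision="round_trip").to_numpy(dtype=float)
            embeddings[f.stem] = emb
    ds = CellDataset(counts=counts, cells=cells, genes=genes,
                     embeddings=embeddings)
    log.info("read %d genes x %d cells (%d embeddings) from %s",
             ds.n_genes, ds.n_cells, len(embeddings), path)
    return ds


def write_dataset(dataset: CellDataset, path: str | Path) -> None:
    """Write a dataset directory with deterministic ordering.

    Explicit zeros are pruned from the sparse matrix, entries are emitted in
    column-major order, and all tables keep their in-memory row order, so
    writing the same dataset twice yields byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = dataset.counts.copy()
    counts.eliminate_zeros()
    counts = counts.tocsc()
    counts.sort_indices()
    scipy.io.mmwrite(path / "matrix.mtx", counts, field="integer"
                     if np.issubdtype(counts.dtype, np.integer) else "real")

    cols = [c for c in CELL_COLUMNS if c in dataset.cells.columns]
    cols += [c for c in dataset.cells.columns if c not in cols]
    dataset.cells[cols].to_csv(path / "cells.tsv", sep="\t", index=False)
    dataset.genes.to_csv(path / "genes.tsv", sep="\t", index=False)

    if dataset.embeddings:
        emb_dir = path / "embeddings"
        emb_dir.mkdir(exist_ok=True)
        for name in sorted(dataset.embeddings):
            emb = dataset.embeddings[name]
            pd.DataFrame(
                emb, columns=[f"dim_{i + 1}" for i in range(emb.shape[1])]
            ).to_csv(emb_dir / f"{name}.tsv", sep="\t", index=False)
    log.info("wrote %d genes x %d cells to %s",
             dataset.n_genes, dataset.n_cells, path)
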