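"""Cell/gene filtering, doublet-subcluster flagging, size factors, pseudobulk.

Filters follow the whole-embryo QC conventions: cells with UMI <= ``umi_min``
or detected genes <= ``gene_min`` are removed, as are cells with
mitochondrial fraction strictly above ``mt_max`` or ribosomal fraction
strictly above ``ribo_max``. Gene filtering drops genes detected in fewer
than ``min_cells`` cells and then cells left expressing fewer than
``min_genes_per_cell`` genes, in that order. Doublet handling takes
externally computed doublet scores: a cell is flagged when its own score
exceeds the threshold, and a whole subcluster is flagged when its fraction of
score-flagged cells exceeds the subcluster threshold (strict inequality in
both cases).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datasets import CellDataset

__all__ = [
    "filter_cells", "filter_genes", "flag_doublet_subclusters",
    "compute_size_factors", "pseudobulk_profiles",
]

log = logging.getLogger("phenoscape.qc")


def filter_cells(dataset: CellDataset, config: PipelineConfig) -> CellDataset:
    """Remove low-quality cells; surviving cell order is preserved."""
    c = dataset.cells
    umi = c["umi_count"].to_numpy(dtype=float)
    ngene = c["gene_count"].to_numpy(dtype=float)
    mt = c["mt_frac"].to_numpy(dtype=float)
    ribo = c["ribo_frac"].to_numpy(dtype=float)
    if np.isnan(umi).any() or np.isnan(ngene).any() or np.isnan(mt).any() \
            or np.isnan(ribo).any():
        raise ValueError(
            "filter_cells requires umi_count, gene_count, mt_frac and "
            "ribo_frac for every cell")
    fail_umi = umi <= config.umi_min
    fail_gene = ngene <= config.gene_min
    fail_mt = mt > config.mt_max
    fail_ribo = ribo > config.ribo_max
    keep = ~(fail_umi | fail_gene | fail_mt | fail_ribo)
    log.info("filter_cells: %d/%d removed (umi<=%d: %d, genes<=%d: %d, "
             "mt>%.2f: %d, ribo>%.2f: %d)",
             (~keep).sum(), len(keep), config.umi_min, fail_umi.sum(),
             config.gene_min, fail_gene.sum(), config.mt_max, fail_mt.sum(),
             config.ribo_max, fail_ribo.sum())
    if not keep.any():
        log.warning("filter_cells removed every cell")
    return dataset.subset_cells(keep)


def filter_genes(dataset: CellDataset, min_cells: int = 10,
                 min_genes_per_cell: int = 100) -> CellDataset:
    """Drop rarely detected genes, then cells left with too few genes."""
    detected = (dataset.counts > 0)
    gene_keep = np.asarray(detected.sum(axis=1)).ravel() >= min_cells
    out = dataset.subset_genes(gene_keep)
    genes_per_cell = np.asarray((out.counts > 0).sum(axis=0)).ravel()
    cell_keep = genes_per_cell >= min_genes_per_cell
    log.info("filter_genes: dropped %d/%d genes (<%d cells), then %d/%d cells "
             "(<%d genes)", (~gene_keep).sum(), len(gene_keep), min_cells,
             (~cell_keep).sum(), len(cell_keep), min_genes_per_cell)
    if not gene_keep.any() or not cell_keep.any():
        log.warning("filter_genes produced an empty dataset")
    return out.subset_cells(cell_keep)


def flag_doublet_subclusters(
    dataset: CellDataset, subcluster_labels, config: PipelineConfig,
) -> np.ndarray:
    """Boolean doublet flags per cell from scores plus the subcluster rule."""
    scores = dataset.cells["doublet_score"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError(
            "doublet scores are missing for some cells; supply externally "
            "computed scores (e.g. Scrublet) in the doublet_score column")
    labels = np.asarray(subcluster_labels)
    if labels.shape != scores.shape:
        raise ValueError("subcluster_labels must cover all cells")
    cell_flag = scores > config.doublet_score_max
    flags = cell_flag.copy()
    for lab in np.unique(labels):
        members = labels == lab
        ratio = cell_flag[members].mean()
        if ratio > config.doublet_subcluster_frac:
            flags[members] = True
            log.info("subcluster %r flagged as doublet-derived "
                     "(%.1f%% flagged cells)", lab, 100 * ratio)
    return flags


def compute_size_factors(totals) -> pd.Series:
    """Per-sample total divided by the geometric mean of all totals.

    The product of the size factors is 1, so the mean log size factor is 0.
    """
    if isinstance(totals, pd.Series):
        index = totals.index
        values = totals.to_numpy(dtype=float)
    else:
        values = np.asarray(totals, dtype=float)
        index = pd.RangeIndex(len(values))
    if (values <= 0).any():
        bad = index[np.flatnonzero(values <= 0)[0]]
        raise ValueError(f"sample {bad!r} has a non-positive total")
    log_t = np.log(values)
    return pd.Series(np.exp(log_t - log_t.mean()), index=index,
                     name="size_factor")


def pseudobulk_profiles(dataset: CellDataset,
                        group_by: str = "embryo_id") -> pd.DataFrame:
    """Sum counts over the cells of each group: a genes x groups matrix."""
    groups = dataset.cells[group_by].astype(str)
    order = list(dict.fromkeys(groups))  # first-appearance order
    mats = {}
    for g in order:
        idx = np.flatnonzero((groups == g).to_numpy())
        mats[g] = np.asarray(dataset.counts[:, idx].sum(axis=1)).ravel()
    return pd.DataFrame(mats, index=dataset.genes["gene_id"].to_numpy())
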