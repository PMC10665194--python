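"""Synthetic multi-embryo cohorts and reference atlases.

The generators emulate the statistical structure of a whole-embryo
single-cell study of mouse development: ~4 replicate embryos per genotype,
tens of cell types with abundances spanning roughly 0.5-20%, ~15,000 cells
recovered per embryo, genotype-specific compositional shifts (an effect size
of 0.1 means a 10% reduction of a cell type's count in mutants), localized
mutant enrichment or depletion in a low-dimensional embedding, and a staged
reference timecourse spanning E9.5-E13.5. Every generator is deterministic
given its design seed.

The Dirichlet concentration controls embryo-to-embryo proportion scatter
(per-embryo sd of a type at proportion p is sqrt(p(1-p)/(c+1))); the default
of 2e4 is derived in docs/methods.md from the requirement that a 25% shift of
a 1%-abundance type be detectable with four replicates per group, the power
regime the composition test is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import CellDataset, CompositionTable, ReferenceAtlas

__all__ = [
    "DEFAULT_BASE_PROPORTIONS",
    "CohortDesign", "EmbeddingDesign", "TimecourseDesign",
    "simulate_composition_cohort", "simulate_embedding_cohort",
    "simulate_expression", "simulate_reference_timecourse",
]

#: Twenty cell-type proportions spanning 0.5%-20% abundance, summing to 1.
DEFAULT_BASE_PROPORTIONS = np.array([
    0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.05, 0.04, 0.035, 0.03,
    0.025, 0.02, 0.018, 0.015, 0.012, 0.01, 0.01, 0.01, 0.01, 0.005,
])
assert abs(DEFAULT_BASE_PROPORTIONS.sum() - 1.0) < 1e-12


def _check_probability_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return p


@dataclass
class CohortDesign:
    """Design of a replicated wild-type/mutant composition cohort.

    ``effect_sizes`` maps cell-type index -> effect in [-1, 1]; mutant counts
    of that type are multiplied by (1 - effect) before rounding, so 0.1 is a
    10% reduction.
    """

    base_proportions: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASE_PROPORTIONS.copy())
    dirichlet_concentration: float = 2e4
    n_wt_embryos: int = 4
    n_mut_embryos: int = 4
    cells_per_embryo_mean: float = 15_000.0
    cells_per_embryo_sd: float = 3_000.0
    effect_sizes: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_proportions = _check_probability_vector(
            self.base_proportions, "base_proportions")
        if self.n_wt_embryos < 1 or self.n_mut_embryos < 1:
            raise ValueError("need at least one embryo per genotype")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.cells_per_embryo_sd < 0:
            raise ValueError("cells_per_embryo_sd must be non-negative")
        for t, e in self.effect_sizes.items():
            if not (0 <= t < self.n_celltypes):
                raise ValueError(f"effect size given for unknown type {t}")
            if not (-1.0 <= e <= 1.0):
                raise ValueError(f"effect size must lie in [-1, 1], got {e}")
        alphas = self.dirichlet_concentration * self.base_proportions
        if not np.all(np.isfinite(alphas)):
            raise ValueError("invalid Dirichlet parameters")

    @property
    def n_celltypes(self) -> int:
        return len(self.base_proportions)


@dataclass
class EmbeddingDesign:
    """Gaussian-mixture embedding with genotype-dependent component weights."""

    component_means: np.ndarray      # (n_components, d), d >= 2
    component_weights_wt: np.ndarray
    component_weights_mut: np.ndarray
    component_cov_scale: float = 1.0
    enriched_component: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.component_means = np.asarray(self.component_means, dtype=float)
        if self.component_means.ndim != 2 or self.component_means.shape[1] < 2:
            raise ValueError("component_means must be (components, d) with d >= 2")
        n = self.n_components
        self.component_weights_wt = _check_probability_vector(
            self.component_weights_wt, "component_weights_wt")
        self.component_weights_mut = _check_probability_vector(
            self.component_weights_mut, "component_weights_mut")
        if len(self.component_weights_wt) != n or len(self.component_weights_mut) != n:
            raise ValueError("weight vectors must have one entry per component")
        if self.component_cov_scale <= 0:
            raise ValueError("component_cov_scale must be positive")
        if self.enriched_component is not None and not (
                0 <= self.enriched_component < n):
            raise ValueError("enriched_component out of range")

    @property
    def n_components(self) -> int:
        return self.component_means.shape[0]


@dataclass
class TimecourseDesign:
    """Staged reference drifting along a fixed embedding axis over time."""

    timepoints: tuple[float, ...] = (9.5, 10.5, 11.5, 12.5, 13.5)
    cells_per_timepoint: int = 500
    drift_per_day: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.cells_per_timepoint < 1:
            raise ValueError("cells_per_timepoint must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_composition_cohort(design: CohortDesign) -> CompositionTable:
    """Draw a wild-type/mutant cohort of embryo x cell-type counts.

    Per-embryo totals are normal (truncated below at 100 cells); per-embryo
    proportions are Dirichlet(concentration x base_proportions); mutant
    embryos have each shifted type's count multiplied by (1 - effect) before
    integer rounding.
    """
    rng = np.random.default_rng(design.seed)
    n_wt, n_mut = design.n_wt_embryos, design.n_mut_embryos
    n_embryos = n_wt + n_mut
    totals = rng.normal(design.cells_per_embryo_mean,
                        design.cells_per_embryo_sd, size=n_embryos)
    totals = np.maximum(100.0, np.rint(totals))
    alphas = design.dirichlet_concentration * design.base_proportions
    props = rng.dirichlet(alphas, size=n_embryos)
    counts = props * totals[:, None]
    shift = np.ones(design.n_celltypes)
    for t, e in design.effect_sizes.items():
        shift[t] = 1.0 - e
    counts[n_wt:] *= shift[None, :]
    counts = np.rint(counts).astype(np.int64)

    embryo_ids = ([f"wt_{i + 1}" for i in range(n_wt)]
                  + [f"mut_{i + 1}" for i in range(n_mut)])
    meta = pd.DataFrame({
        "embryo_id": embryo_ids,
        "genotype": ["wt"] * n_wt + ["mut"] * n_mut,
        "background": "B6",
    })
    counts_df = pd.DataFrame(
        counts, index=pd.Index(embryo_ids, name="embryo_id"),
        columns=[f"type_{t:02d}" for t in range(design.n_celltypes)])
    from .qc import compute_size_factors
    sf = compute_size_factors(counts_df.sum(axis=1))
    return CompositionTable(counts=counts_df, embryo_meta=meta, size_factors=sf)


def simulate_embedding_cohort(
    design: EmbeddingDesign, n_embryos_per_genotype: int, cells_per_embryo: int,
) -> CellDataset:
    """Sample a multi-embryo cohort of embedding coordinates.

    Wild-type and mutant cells draw mixture components from their respective
    weight vectors, so the ``enriched_component`` is over- or
    under-represented among mutant cells. The returned dataset carries the
    coordinates as embedding ``"pca"`` and the component membership as the
    ``sub_trajectory`` annotation; the count matrix is empty (0 genes) until
    :func:`simulate_expression` adds one.
    """
    if cells_per_embryo < 10 * design.n_components:
        raise ValueError(
            "cells_per_embryo must be at least 10 x n_components "
            "(degenerate mixture sampling)")
    rng = np.random.default_rng(design.seed)
    d = design.component_means.shape[1]
    rows, coords_list = [], []
    for genotype, weights in (("wt", design.component_weights_wt),
                              ("mut", design.component_weights_mut)):
        for e in range(n_embryos_per_genotype):
            comp = rng.choice(design.n_components, size=cells_per_embryo,
                              p=weights)
            xy = (design.component_means[comp]
                  + rng.normal(scale=design.component_cov_scale,
                               size=(cells_per_embryo, d)))
            coords_list.append(xy)
            embryo = f"{genotype}_{e + 1}"
            for c in comp:
                rows.append((embryo, genotype, f"component_{c}"))
    coords = np.vstack(coords_list)
    cells = pd.DataFrame(rows, columns=["embryo_id", "genotype",
                                        "sub_trajectory"])
    cells.insert(0, "cell_id", [f"cell_{i:06d}" for i in range(len(cells))])
    cells["background"] = "B6"
    genes = pd.DataFrame({"gene_id": [], "gene_name": []}, dtype=str)
    counts = sp.csr_matrix((0, len(cells)), dtype=np.int64)
    return CellDataset(counts=counts, cells=cells, genes=genes,
                       embeddings={"pca": coords})


def simulate_expression(
    dataset: CellDataset,
    n_genes: int,
    linked_genes: dict[int, float],
    seed: int = 0,
    covariate: str | np.ndarray = "lochness",
    dispersion: float = 0.5,
    baseline_mean: float = 0.3,
) -> CellDataset:
    """Add a sparse count matrix whose linked genes track a per-cell covariate.

    Baseline counts are gamma-Poisson (negative-binomial-like) with the given
    dispersion; for each linked gene the log-mean is shifted by
    ``slope x covariate``. Library sizes vary threefold across cells, so any
    downstream regression must use a size-factor offset.
    """
    if n_genes < len(linked_genes):
        raise ValueError("n_genes must be at least the number of linked genes")
    for g in linked_genes:
        if not (0 <= g < n_genes):
            raise ValueError(f"linked gene index {g} out of range")
    if isinstance(covariate, str):
        if covariate not in dataset.cells.columns:
            raise ValueError(
                f"dataset has no per-cell covariate column {covariate!r}")
        cov = dataset.cells[covariate].to_numpy(dtype=float)
    else:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != (dataset.n_cells,):
            raise ValueError("covariate must have one value per cell")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite for every cell")

    rng = np.random.default_rng(seed)
    n_cells = dataset.n_cells
    # >= 2-fold library-size spread by construction (3-fold range in log)
    lib = np.exp(rng.uniform(np.log(0.6), np.log(1.8), size=n_cells))
    gene_mean = baseline_mean * np.exp(rng.normal(0.0, 0.6, size=n_genes))
    slopes = np.zeros(n_genes)
    for g, s in linked_genes.items():
        slopes[g] = s

    shape = 1.0 / dispersion
    cols, rows_idx, data = [], [], []
    for g in range(n_genes):
        rate = lib * gene_mean[g] * np.exp(slopes[g] * cov)
        lam = rng.gamma(shape, scale=rate * dispersion)
        y = rng.poisson(lam)
        nz = np.flatnonzero(y)
        rows_idx.append(np.full(nz.size, g, dtype=np.int64))
        cols.append(nz)
        data.append(y[nz])
    counts = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows_idx), np.concatenate(cols))),
        shape=(n_genes, n_cells), dtype=np.int64)

    genes = pd.DataFrame({
        "gene_id": [f"gene_{g:05d}" for g in range(n_genes)],
        "gene_name": [f"Gene{g}" for g in range(n_genes)],
    })
    cells = dataset.cells.copy()
    cells["umi_count"] = np.asarray(counts.sum(axis=0)).ravel()
    cells["gene_count"] = np.asarray((counts > 0).sum(axis=0)).ravel()
    return CellDataset(counts=counts, cells=cells, genes=genes,
                       embeddings=dict(dataset.embeddings))


def simulate_reference_timecourse(design: TimecourseDesign) -> ReferenceAtlas:
    """Staged reference atlas drifting along the first embedding axis."""
    rng = np.random.default_rng(design.seed)
    tp = np.asarray(design.timepoints, dtype=float)
    t0 = tp[0]
    coords, times = [], []
    for t in tp:
        centre = np.array([design.drift_per_day * (t - t0), 0.0])
        xy = centre + rng.normal(scale=design.noise_sd,
                                 size=(design.cells_per_timepoint, 2))
        coords.append(xy)
        times.append(np.full(design.cells_per_timepoint, t))
    return ReferenceAtlas(coords=np.vstack(coords),
                          times=np.concatenate(times))
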