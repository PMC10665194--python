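"""Embryo/genotype similarity matrices and developmental time scores.

The similarity score between cell n and embryo j is the observed over
expected fraction of embryo-j cells among n's k nearest neighbours (the cell
itself excluded; k = round(sqrt(N)/2) as for lochNESS):

    sim(n, j) = (neighbours from j / k) / (n_j / N)

Averaging over the cells of embryo i gives the embryo x embryo matrix; under
exchangeable cell positions every entry is ~1, and embryos sharing a mutant
phenotype score above 1 with each other. The matrix is directional
(observed/expected from i's neighbourhoods), so it need not be symmetric.

Time scores place query cells on a staged reference atlas: the score is the
mean developmental time of the k nearest reference cells, and a delay is
called when mutant cells score significantly younger than wild-type cells
(two-sided Welch t-test; an embryo-level aggregation mode is available since
cell-level testing pseudoreplicates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import ReferenceAtlas
from .lochness import choose_k
from .neighbors import knn_indices

__all__ = [
    "SimilarityMatrix", "EmbryoSimilarity", "embryo_similarity",
    "genotype_similarity", "TimeScorer", "time_scores", "delay_test",
]

log = logging.getLogger("phenoscape.similarity")


@dataclass
class SimilarityMatrix:
    """Embryo x embryo observed/expected neighbourhood similarity."""

    embryo_ids: list
    matrix: pd.DataFrame            # rows: scored embryo i, cols: target j
    n_cells_per_embryo: pd.Series
    k: int
    flagged_small: list             # embryos with < 5 cells


class EmbryoSimilarity(BaseEstimator):
    """Observed/expected neighbour composition per embryo pair.

    Attributes (after :meth:`fit`): ``matrix_`` (DataFrame, rows scored
    embryo, columns target embryo), ``k_``, ``n_cells_per_embryo_``.
    """

    def __init__(self, k="auto"):
        self.k = k

    def fit(self, coords, embryo_id) -> "EmbryoSimilarity":
        coords = np.asarray(coords, dtype=float)
        embryo_id = np.asarray(embryo_id)
        n = coords.shape[0]
        if embryo_id.shape != (n,):
            raise ValueError("embryo_id must be per-cell")
        ids, codes = np.unique(embryo_id, return_inverse=True)
        if len(ids) < 2:
            raise ValueError("need at least 2 embryos")
        k = choose_k(n) if self.k == "auto" else int(self.k)
        idx = knn_indices(coords, k, exclude_self=True)
        n_j = np.bincount(codes, minlength=len(ids)).astype(float)
        small = [str(ids[j]) for j in np.flatnonzero(n_j < 5)]
        if small:
            log.warning("embryos with <5 cells flagged: %s", small)
        # per-cell counts of neighbours per embryo
        neigh_codes = codes[idx]                       # (n, k)
        counts = np.zeros((n, len(ids)))
        for j in range(len(ids)):
            counts[:, j] = (neigh_codes == j).sum(axis=1)
        assert np.all(counts.sum(axis=1) == k)  # conservation identity
        expected = n_j / n
        cell_scores = (counts / k) / expected[None, :]
        mat = np.empty((len(ids), len(ids)))
        for i in range(len(ids)):
            mat[i] = cell_scores[codes == i].mean(axis=0)
        self.matrix_ = pd.DataFrame(mat, index=ids, columns=ids)
        self.k_ = k
        self.n_cells_per_embryo_ = pd.Series(n_j.astype(int), index=ids)
        self.flagged_small_ = small
        return self

    def result(self) -> SimilarityMatrix:
        return SimilarityMatrix(
            embryo_ids=list(self.matrix_.index), matrix=self.matrix_,
            n_cells_per_embryo=self.n_cells_per_embryo_, k=self.k_,
            flagged_small=self.flagged_small_)


def embryo_similarity(coords, embryo_id, k="auto") -> SimilarityMatrix:
    """Embryo x embryo similarity matrix (see module docstring)."""
    return EmbryoSimilarity(k=k).fit(coords, embryo_id).result()


def genotype_similarity(sim: SimilarityMatrix, genotype_of_embryo,
                        mode: str = "embryo_first") -> pd.DataFrame:
    """Mean embryo-level similarity within each genotype pair.

    Self-pairs of the same embryo are excluded from the diagonal. The result
    is directional like the embryo matrix. ``mode="embryo_first"`` averages
    the embryo-level entries (default); ``"cell_first"`` weights each scored
    embryo by its cell count.
    """
    geno = pd.Series(genotype_of_embryo)
    if not set(sim.matrix.index) <= set(geno.index):
        geno = pd.Series(genotype_of_embryo, index=sim.matrix.index)
    genotypes = sorted(geno.unique())
    out = pd.DataFrame(np.nan, index=genotypes, columns=genotypes)
    weights = sim.n_cells_per_embryo if mode == "cell_first" else None
    for ga in genotypes:
        rows = [e for e in sim.matrix.index if geno[e] == ga]
        for gb in genotypes:
            cols = [e for e in sim.matrix.columns if geno[e] == gb]
            vals, w = [], []
            for i in rows:
                for j in cols:
                    if i == j:
                        continue
                    vals.append(sim.matrix.loc[i, j])
                    w.append(1.0 if weights is None else weights[i])
            if vals:
                out.loc[ga, gb] = np.average(vals, weights=w)
    return out


class TimeScorer(BaseEstimator, RegressorMixin):
    """Mean developmental time of the k nearest reference cells.

    Fit on a staged reference atlas; predict returns per-query time scores,
    always inside the reference time range.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, reference_coords, reference_times=None) -> "TimeScorer":
        if isinstance(reference_coords, ReferenceAtlas):
            atlas = reference_coords
            reference_coords, reference_times = atlas.coords, atlas.times
        coords = np.asarray(reference_coords, dtype=float)
        times = np.asarray(reference_times, dtype=float)
        if self.k > coords.shape[0]:
            raise ValueError(
                f"k={self.k} exceeds reference size {coords.shape[0]}")
        self.reference_coords_ = coords
        self.reference_times_ = times
        return self

    def predict(self, query_coords) -> np.ndarray:
        query = np.asarray(query_coords, dtype=float)
        idx = knn_indices(self.reference_coords_, self.k, query=query,
                          exclude_self=False)
        return self.reference_times_[idx].mean(axis=1)


def time_scores(query_coords, reference: ReferenceAtlas,
                k: int = 10) -> np.ndarray:
    """Per-query mean reference time over the k nearest reference cells."""
    return TimeScorer(k=k).fit(reference).predict(query_coords)


def delay_test(scores_mut, scores_wt,
               embryo_mut=None, embryo_wt=None) -> tuple[float, float]:
    """Welch t-test of mutant vs wild-type time scores (two-sided).

    Negative t means mutant cells score younger (developmental delay). When
    embryo labels are given, scores are first averaged per embryo to avoid
    pseudoreplication. Degenerate zero-variance inputs return p = 1 when the
    means are equal and p = 0 otherwise.
    """
    a = np.asarray(scores_mut, dtype=float)
    b = np.asarray(scores_wt, dtype=float)
    if embryo_mut is not None:
        a = pd.Series(a).groupby(np.asarray(embryo_mut)).mean().to_numpy()
    if embryo_wt is not None:
        b = pd.Series(b).groupby(np.asarray(embryo_wt)).mean().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 scores per group")
    if a.std() == 0 and b.std() == 0:
        log.warning("zero variance in both groups; degenerate t-test")
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
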