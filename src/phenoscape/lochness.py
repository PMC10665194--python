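"""Per-cell neighbourhood enrichment of mutant cells (lochNESS) and its null.

For a co-embedding of one mutant's cells with a pooled wild type, each cell's
score is the fold change of the mutant fraction among its k nearest
neighbours (cells from the same embryo excluded) over the dataset-wide mutant
fraction m/N, minus 1:

    score = (mutant neighbours / k) / (m / N) - 1

so 0 means a well-mixed neighbourhood, -1 means no mutant neighbours, and the
maximum is 1/(m/N) - 1. The neighbourhood size k = round(sqrt(N)/2) scales
with the dataset. A null is obtained by permuting genotype labels over cells
(the neighbour graph does not depend on labels and is reused); the deviance
of a score vector is the average Euclidean distance to its permuted versions,
normalized per cell (RMS) so that sub-trajectories of different sizes are
comparable. Screening ranks sub-trajectories by deviance to find shifted
distributions; gene-level regression finds genes whose expression tracks the
score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .neighbors import knn_distances_indices, knn_indices

__all__ = [
    "choose_k", "LochnessResult", "LochNESS", "compute_lochness",
    "lochness_null", "lochness_deviance", "screen_distributions",
    "lochness_gene_assoc", "compute_lisi",
]

log = logging.getLogger("phenoscape.lochness")


def choose_k(n_total: int) -> int:
    """Neighbourhood size round(sqrt(N)/2), at least 1 (round-half-even)."""
    if n_total < 4:
        raise ValueError("need at least 4 cells")
    return max(1, int(np.round(np.sqrt(n_total) / 2.0)))


@dataclass
class LochnessResult:
    """Per-cell scores with the quantities needed to interpret them."""

    scores: np.ndarray
    k: int
    n_total: int
    n_mut: int
    mut_fraction: float
    perm_scores: np.ndarray | None = None   # (cells, R)
    deviance: float | None = None
    group_labels: np.ndarray | None = None


class LochNESS(BaseEstimator):
    """Neighbourhood mutant-enrichment scorer.

    Parameters
    ----------
    k
        Neighbourhood size, or ``"auto"`` for round(sqrt(N)/2).
    n_permutations
        Label permutations for the null (0 skips the null).
    permutation_unit
        ``"cell"`` (default) shuffles genotype labels over cells;
        ``"embryo"`` shuffles the embryo -> genotype assignment instead,
        preserving within-embryo label blocks for users worried about
        within-embryo correlation.
    random_state
        Seed for the permutation stream.

    Attributes
    ----------
    scores_, k_, n_total_, n_mut_, mut_fraction_, neighbor_idx_,
    perm_scores_, deviance_
    """

    def __init__(self, k="auto", n_permutations: int = 0,
                 permutation_unit: str = "cell",
                 random_state: int | None = None):
        self.k = k
        self.n_permutations = n_permutations
        self.permutation_unit = permutation_unit
        self.random_state = random_state

    def fit(self, coords, genotype, embryo_id) -> "LochNESS":
        coords = np.asarray(coords, dtype=float)
        genotype = np.asarray(genotype).astype(bool)
        embryo_id = np.asarray(embryo_id)
        n = coords.shape[0]
        if genotype.shape != (n,) or embryo_id.shape != (n,):
            raise ValueError("genotype and embryo_id must be per-cell")
        m = int(genotype.sum())
        if m == 0 or m == n:
            raise ValueError("need at least one mutant and one non-mutant cell")
        k = choose_k(n) if self.k == "auto" else int(self.k)
        _, embryo_sizes = np.unique(embryo_id, return_counts=True)
        if embryo_sizes.max() > n - k:
            raise ValueError(
                "an embryo holds more than N - k cells; neighbourhoods "
                "excluding its own embryo cannot be filled")
        idx = knn_indices(coords, k, exclude_groups=embryo_id)
        mut_frac = m / n
        counts = genotype[idx].sum(axis=1)
        self.scores_ = (counts / k) / mut_frac - 1.0
        self.neighbor_idx_ = idx
        self.k_, self.n_total_, self.n_mut_ = k, n, m
        self.mut_fraction_ = mut_frac
        self.perm_scores_ = None
        self.deviance_ = None
        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            perms = np.empty((n, self.n_permutations))
            if self.permutation_unit == "cell":
                for r in range(self.n_permutations):
                    lab = rng.permutation(genotype)
                    perms[:, r] = (lab[idx].sum(axis=1) / k) / mut_frac - 1.0
            elif self.permutation_unit == "embryo":
                ids, codes = np.unique(embryo_id, return_inverse=True)
                emb_geno = np.array([genotype[codes == i][0]
                                     for i in range(len(ids))])
                if not all(len(set(genotype[codes == i])) == 1
                           for i in range(len(ids))):
                    raise ValueError(
                        "embryo-level permutation requires genotype to be "
                        "constant within each embryo")
                for r in range(self.n_permutations):
                    lab = rng.permutation(emb_geno)[codes]
                    frac = lab.mean()
                    perms[:, r] = (lab[idx].sum(axis=1) / k) / frac - 1.0
            else:
                raise ValueError("permutation_unit must be 'cell' or 'embryo'")
            self.perm_scores_ = perms
            self.deviance_ = lochness_deviance(self.scores_, perms)
        return self

    def result(self, group_labels=None) -> LochnessResult:
        return LochnessResult(
            scores=self.scores_, k=self.k_, n_total=self.n_total_,
            n_mut=self.n_mut_, mut_fraction=self.mut_fraction_,
            perm_scores=self.perm_scores_, deviance=self.deviance_,
            group_labels=None if group_labels is None
            else np.asarray(group_labels))


def compute_lochness(coords, genotype, embryo_id, k="auto") -> LochnessResult:
    """Per-cell mutant-enrichment scores (see module docstring)."""
    return LochNESS(k=k).fit(coords, genotype, embryo_id).result()


def lochness_null(coords, genotype, embryo_id, k="auto",
                  n_permutations: int = 100,
                  seed: int | None = None) -> np.ndarray:
    """(cells x R) scores under random genotype-label permutation."""
    est = LochNESS(k=k, n_permutations=n_permutations, random_state=seed)
    est.fit(coords, genotype, embryo_id)
    return est.perm_scores_


def lochness_deviance(observed: np.ndarray, perm_scores: np.ndarray,
                      pairing: str = "per_cell",
                      normalize: bool = True) -> float:
    """Mean over permutations of ||observed - perm||_2 / sqrt(n_cells).

    ``pairing="per_cell"`` (default) pairs observed and permuted scores cell
    by cell; ``"sorted"`` compares the sorted score distributions instead,
    which ignores where in the embedding the shift sits. ``normalize=False``
    returns the raw Euclidean distance (scales with sqrt(n_cells)).
    """
    observed = np.asarray(observed, dtype=float)
    perm_scores = np.asarray(perm_scores, dtype=float)
    if perm_scores.shape[0] != observed.shape[0]:
        raise ValueError("perm_scores must have one row per cell")
    if pairing == "sorted":
        observed = np.sort(observed)
        perm_scores = np.sort(perm_scores, axis=0)
    elif pairing != "per_cell":
        raise ValueError("pairing must be 'per_cell' or 'sorted'")
    diffs = perm_scores - observed[:, None]
    norms = np.sqrt((diffs ** 2).sum(axis=0))
    if normalize:
        norms = norms / np.sqrt(len(observed))
    return float(norms.mean())


def screen_distributions(result: LochnessResult, group_labels=None,
                         min_cells: int = 20) -> pd.DataFrame:
    """Per-group score summaries, sorted by deviance.

    For every sub-trajectory (group): cell count, median score, per-cell RMS
    deviance against the permutation null, and a two-sample KS statistic of
    the observed scores versus the pooled permuted scores of that group.
    Groups with fewer than ``min_cells`` cells are flagged low-confidence.
    """
    if result.perm_scores is None:
        raise ValueError("screening requires permutation scores")
    labels = result.group_labels if group_labels is None \
        else np.asarray(group_labels)
    if labels is None:
        raise ValueError("group labels are required")
    rows = []
    for g in np.unique(labels):
        members = labels == g
        obs = result.scores[members]
        perm = result.perm_scores[members]
        ks = stats.ks_2samp(obs, perm.ravel())
        rows.append({
            "group": g, "n_cells": int(members.sum()),
            "median_score": float(np.median(obs)),
            "deviance": lochness_deviance(obs, perm),
            "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue),
            "low_confidence": bool(members.sum() < min_cells),
        })
    return (pd.DataFrame(rows)
            .sort_values("deviance", ascending=False)
            .reset_index(drop=True))


def lochness_gene_assoc(counts, scores, size_factors,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene regression of expression on the enrichment score.

    Fits, for each gene, an overdispersed (quasi-Poisson) log-link count
    regression with log size factor as offset; the score coefficient is
    tested by a Wald test and p-values are Benjamini-Hochberg adjusted across
    genes. Genes with adjusted p < alpha are called enriched-area (positive
    coefficient) or depleted-area (negative) associated. Genes with zero
    total count are reported untested.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_cells = counts.shape[1]
    if n_cells < 50:
        raise ValueError("need at least 50 cells for gene regression")
    if scores.shape != (n_cells,):
        raise ValueError("scores must have one value per cell")
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    offset = np.log(sf)
    X = sm.add_constant(scores)
    betas = np.full(counts.shape[0], np.nan)
    pvals = np.full(counts.shape[0], np.nan)
    dense = counts.tocsr() if hasattr(counts, "tocsr") else np.asarray(counts)
    for g in range(counts.shape[0]):
        y = (dense[g].toarray().ravel() if hasattr(dense, "tocsr")
             else dense[g])
        if y.sum() == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Poisson(),
                             offset=offset).fit(scale="X2")
            betas[g] = res.params[1]
            pvals[g] = res.pvalues[1]
        except Exception as exc:  # pragma: no cover - degenerate genes
            log.debug("gene %d regression failed: %s", g, exc)
    tested = np.isfinite(pvals)
    qvals = np.full_like(pvals, np.nan)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    direction = np.where(~tested | (qvals >= alpha), "ns",
                         np.where(betas > 0, "enriched", "depleted"))
    return pd.DataFrame({
        "gene_index": np.arange(counts.shape[0]),
        "beta": betas, "p_value": pvals, "q_value": qvals,
        "tested": tested, "association": direction,
    })


def compute_lisi(coords, labels, perplexity: int | None = None) -> np.ndarray:
    """Local inverse Simpson index of label mixing, in [1, n_labels].

    Gaussian-kernel neighbourhood weights are tuned per cell so the weight
    entropy matches ``log(perplexity)``, over K = 3 x perplexity neighbours.
    The default perplexity is floor(0.5 sqrt(N/3)), scaled to the dataset
    like the lochNESS neighbourhood; values below 1 are clamped with a
    warning. For two labels, scores near 1 mean separated and near 2
    perfectly mixed neighbourhoods.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = coords.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must be per-cell")
    if perplexity is None:
        perplexity = int(np.floor(0.5 * np.sqrt(n / 3.0)))
    if perplexity < 1:
        warnings.warn("perplexity < 1; clamped to 1", UserWarning,
                      stacklevel=2)
        perplexity = 1
    K = min(3 * perplexity, n - 1)
    dist, idx = knn_distances_indices(coords, K, exclude_self=True)
    d2 = dist ** 2
    target = np.log(perplexity)
    uniq, lab_codes = np.unique(labels, return_inverse=True)
    out = np.empty(n)
    for i in range(n):
        beta_lo, beta_hi, beta = 0.0, np.inf, 1.0 / max(d2[i].mean(), 1e-12)
        for _ in range(60):
            w = np.exp(-beta * d2[i])
            s = w.sum()
            if s <= 0:
                h = 0.0
            else:
                p = w / s
                h = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(h - target) < 1e-5:
                break
            if h > target:
                beta_lo = beta
                beta = beta * 2 if not np.isfinite(beta_hi) \
                    else 0.5 * (beta_lo + beta_hi)
            else:
                beta_hi = beta
                beta = 0.5 * (beta_lo + beta_hi)
        w = np.exp(-beta * d2[i])
        s = w.sum()
        if s <= 0:  # all weight collapsed: neighbourhood of one point
            out[i] = 1.0
            continue
        p = w / s
        simpson = sum(p[lab_codes[idx[i]] == c].sum() ** 2
                      for c in range(len(uniq)))
        out[i] = 1.0 / simpson
    return out
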