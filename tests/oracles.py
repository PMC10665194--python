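"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: neighbour
search is an explicit per-cell sort of all pairwise distances with the shared
tie-break (lower index wins), and the beta-binomial oracle is a two-stage
dense grid search over (intercept, coefficient, rho).
"""

from __future__ import annotations

import numpy as np

from phenoscape.composition import betabinom_loglik
from scipy.special import logit


def brute_knn(coords, k, *, exclude_embryo=None, embryo=None,
              exclude_self=True):
    """Per-cell k nearest neighbours by exhaustive sorted scan."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    out = []
    for i in range(n):
        d2 = ((coords - coords[i]) ** 2).sum(axis=1)
        cand = []
        for j in range(n):
            if exclude_self and j == i:
                continue
            if exclude_embryo is not None and embryo[j] == embryo[i]:
                continue
            cand.append((d2[j], j))
        cand.sort()
        out.append([j for _, j in cand[:k]])
    return np.asarray(out)


def brute_lochness(coords, genotype, embryo, k):
    genotype = np.asarray(genotype).astype(bool)
    idx = brute_knn(coords, k, exclude_embryo=True, embryo=np.asarray(embryo))
    m, n = genotype.sum(), len(genotype)
    return np.array([(genotype[row].sum() / k) / (m / n) - 1.0
                     for row in idx])


def brute_similarity(coords, embryo, k):
    embryo = np.asarray(embryo)
    ids = np.unique(embryo)
    n = len(embryo)
    idx = brute_knn(coords, k, exclude_self=True)
    cell_scores = np.empty((n, len(ids)))
    for i, row in enumerate(idx):
        for jj, e in enumerate(ids):
            cnt = sum(1 for j in row if embryo[j] == e)
            cell_scores[i, jj] = (cnt / k) / ((embryo == e).sum() / n)
    mat = np.empty((len(ids), len(ids)))
    for ii, e in enumerate(ids):
        mat[ii] = cell_scores[embryo == e].mean(axis=0)
    return ids, mat


def brute_label_transfer(ref_coords, ref_labels, query_coords, k):
    """Majority vote; ties by min mean neighbour distance then label order."""
    ref_coords = np.asarray(ref_coords, dtype=float)
    ref_labels = np.asarray(ref_labels)
    labels, scores = [], []
    for q in np.asarray(query_coords, dtype=float):
        d2 = ((ref_coords - q) ** 2).sum(axis=1)
        order = sorted(range(len(d2)), key=lambda j: (d2[j], j))[:k]
        votes = {}
        for j in order:
            lab = ref_labels[j]
            cnt, tot = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, tot + np.sqrt(d2[j]))
        best = sorted(votes.items(),
                      key=lambda kv: (-kv[1][0], kv[1][1] / kv[1][0],
                                      str(kv[0])))[0]
        labels.append(best[0])
        scores.append(best[1][0] / k)
    return np.asarray(labels), np.asarray(scores)


def grid_search_betabinom(k, n, x, n_coarse=25, n_fine=21, refine=3):
    """Best log-likelihood over a dense, iteratively refined parameter grid."""
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    x = np.asarray(x, float)
    p_hat = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    b0_lo, b0_hi = logit(p_hat) - 2.0, logit(p_hat) + 2.0
    b1_lo, b1_hi = -3.0, 3.0
    zr_lo, zr_hi = logit(1e-6), logit(0.5)
    best = (-np.inf, None)
    for _ in range(refine):
        b0s = np.linspace(b0_lo, b0_hi, n_coarse)
        b1s = np.linspace(b1_lo, b1_hi, n_coarse)
        zrs = np.linspace(zr_lo, zr_hi, n_fine)
        for b0 in b0s:
            for b1 in b1s:
                for zr in zrs:
                    ll = betabinom_loglik(np.array([b0, b1, zr]), k, n, x)
                    if ll > best[0]:
                        best = (ll, (b0, b1, zr))
        b0, b1, zr = best[1]
        w0 = (b0_hi - b0_lo) / (n_coarse - 1)
        w1 = (b1_hi - b1_lo) / (n_coarse - 1)
        wz = (zr_hi - zr_lo) / (n_fine - 1)
        b0_lo, b0_hi = b0 - 2 * w0, b0 + 2 * w0
        b1_lo, b1_hi = b1 - 2 * w1, b1 + 2 * w1
        zr_lo, zr_hi = zr - 2 * wz, zr + 2 * wz
    return best[0]


def mom_dirichlet_mean(counts):
    """Method-of-moments mean proportions from an embryo x type count matrix."""
    props = counts / counts.sum(axis=1, keepdims=True)
    return props.mean(axis=0)
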