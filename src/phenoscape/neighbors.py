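"""Exact k-nearest-neighbour search with deterministic tie-breaking.

All neighbourhood statistics in this package (lochNESS, similarity scores,
label transfer, time scores) are defined on exact Euclidean kNN graphs and are
validated against exhaustive oracles, so neighbour search is done with full
pairwise distances (chunked over query cells to bound memory) rather than an
approximate index. Ties at equal distance keep the lower cell index, which
makes every downstream score reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["knn_indices", "knn_distances_indices"]

_CHUNK = 1024


def _neighbour_order(d2: np.ndarray, k: int) -> np.ndarray:
    # stable argsort on squared distances: equal values keep ascending index
    return np.argsort(d2, axis=1, kind="stable")[:, :k]


def knn_indices(
    coords: np.ndarray,
    k: int,
    *,
    query: np.ndarray | None = None,
    exclude_groups: np.ndarray | None = None,
    query_groups: np.ndarray | None = None,
    exclude_self: bool = True,
) -> np.ndarray:
    """Indices of the k nearest reference points for each query point.

    Parameters
    ----------
    coords
        Reference coordinates, shape (n_ref, d).
    k
        Neighbourhood size.
    query
        Query coordinates; defaults to ``coords`` (self-query), in which case
        ``exclude_self`` removes each point from its own neighbourhood.
    exclude_groups, query_groups
        Per-reference and per-query group labels (e.g. embryo ids); reference
        points sharing the query's group are excluded from its neighbourhood.
    """
    coords = np.asarray(coords, dtype=float)
    self_query = query is None
    q = coords if self_query else np.asarray(query, dtype=float)
    if q.shape[1] != coords.shape[1]:
        raise ValueError("query and reference dimensionality differ")
    n_ref = coords.shape[0]
    if exclude_groups is not None:
        exclude_groups = np.asarray(exclude_groups)
        if self_query and query_groups is None:
            query_groups = exclude_groups
        query_groups = np.asarray(query_groups)

    out = np.empty((q.shape[0], k), dtype=np.int64)
    for start in range(0, q.shape[0], _CHUNK):
        stop = min(start + _CHUNK, q.shape[0])
        d2 = cdist(q[start:stop], coords, metric="sqeuclidean")
        if self_query and exclude_self:
            rows = np.arange(start, stop)
            d2[np.arange(stop - start), rows] = np.inf
        if exclude_groups is not None:
            mask = query_groups[start:stop, None] == exclude_groups[None, :]
            d2[mask] = np.inf
        if np.isfinite(d2).sum(axis=1).min() < k:
            raise ValueError(
                "fewer than k admissible neighbours for some query point")
        out[start:stop] = _neighbour_order(d2, k)
    return out


def knn_distances_indices(
    coords: np.ndarray, k: int, *, query: np.ndarray | None = None,
    exclude_self: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`knn_indices` but also returns Euclidean distances."""
    coords = np.asarray(coords, dtype=float)
    self_query = query is None
    q = coords if self_query else np.asarray(query, dtype=float)
    idx = np.empty((q.shape[0], k), dtype=np.int64)
    dist = np.empty((q.shape[0], k), dtype=float)
    for start in range(0, q.shape[0], _CHUNK):
        stop = min(start + _CHUNK, q.shape[0])
        d2 = cdist(q[start:stop], coords, metric="sqeuclidean")
        if self_query and exclude_self:
            d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = _neighbour_order(d2, k)
        idx[start:stop] = order
        dist[start:stop] = np.sqrt(
            np.take_along_axis(d2, order, axis=1))
    return dist, idx
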