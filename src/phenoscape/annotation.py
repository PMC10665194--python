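"""Label transfer from a wild-type reference embedding by k-NN vote.

Each query cell takes the majority label among its k Euclidean nearest
reference cells, with the vote fraction reported as the assigned score
(maximum label frequency / k). Scores at or below 0.8 are flagged for review.
Ties are broken by the smallest mean neighbour distance, then
lexicographically, so results are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .neighbors import knn_distances_indices

__all__ = ["KNNLabelTransfer", "knn_label_transfer"]

LOW_SCORE_FLAG = 0.8


class KNNLabelTransfer(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour vote classifier with an assigned-score confidence.

    Parameters
    ----------
    k
        Neighbourhood size (default 15).

    Attributes
    ----------
    reference_ : (n_ref, d) reference coordinates
    labels_ : per-reference labels
    classes_ : sorted unique labels
    """

    def __init__(self, k: int = 15):
        self.k = k

    def fit(self, X, y) -> "KNNLabelTransfer":
        X = check_array(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if self.k > X.shape[0]:
            raise ValueError(
                f"k={self.k} exceeds the reference size {X.shape[0]}")
        self.reference_ = X
        self.labels_ = y
        self.classes_ = np.unique(y)
        return self

    def transfer(self, X) -> pd.DataFrame:
        """Per-query assigned_label, assigned_score, k_used and review flag."""
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.reference_.shape[1]:
            raise ValueError("query dimensionality differs from reference")
        dist, idx = knn_distances_indices(
            self.reference_, self.k, query=X, exclude_self=False)
        labels, scores = [], []
        for row_idx, row_dist in zip(idx, dist):
            votes: dict = {}
            for j, dj in zip(row_idx, row_dist):
                lab = self.labels_[j]
                cnt, tot = votes.get(lab, (0, 0.0))
                votes[lab] = (cnt + 1, tot + dj)
            best = max(votes.items(),
                       key=lambda kv: (kv[1][0],            # max frequency
                                       -kv[1][1] / kv[1][0],  # min mean dist
                                       _inv_lex(kv[0])))
            labels.append(best[0])
            scores.append(best[1][0] / self.k)
        scores = np.asarray(scores)
        return pd.DataFrame({
            "assigned_label": labels,
            "assigned_score": scores,
            "k_used": self.k,
            "low_score_flag": scores <= LOW_SCORE_FLAG,
        })

    def predict(self, X) -> np.ndarray:
        return self.transfer(X)["assigned_label"].to_numpy()


class _inv_lex:
    """Ordering helper: under max(), prefers the lexicographically smaller label."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __lt__(self, other):  # self "smaller" when label sorts later
        return str(self.v) > str(other.v)


def knn_label_transfer(reference_coords, reference_labels, query_coords,
                       k: int = 15) -> pd.DataFrame:
    """Functional wrapper over :class:`KNNLabelTransfer`."""
    return KNNLabelTransfer(k=k).fit(
        reference_coords, reference_labels).transfer(query_coords)
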