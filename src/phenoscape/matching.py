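"""Cross-atlas trajectory matching by reciprocal non-negative least squares.

Aggregate expression profiles (sum of log-transformed normalized counts over
the cells of each trajectory) from two atlases are compared by predicting
each target trajectory's profile from all trajectories of the other atlas
under NNLS, on the union of the target's 3,000 most highly expressed and
3,000 most specific genes. The two directional coefficients for a pair (a, b)
are combined as

    combined(a, b) = 2 (beta_ab + 0.001) (beta_ba + 0.001)

which is high only for reciprocal, specific predictivity; each trajectory's
best match is the argmax of the combined score. Specificity of a gene for a
target is its share of the gene's aggregate signal across trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

__all__ = ["TrajectoryMatch", "TrajectoryMatcher", "select_signature_genes",
           "nnls_predict", "reciprocal_match"]

NNLS_OFFSET = 0.001


@dataclass
class TrajectoryMatch:
    """Reciprocal NNLS coefficients and combined match scores."""

    trajectories_a: list
    trajectories_b: list
    beta_ab: pd.DataFrame     # rows: target a, cols: predictor b
    beta_ba: pd.DataFrame     # rows: target b, cols: predictor a
    combined: pd.DataFrame    # rows: a, cols: b
    best_match: pd.Series     # per trajectory a, the argmax b
    gene_sets: dict           # ("a"|"b", trajectory) -> gene list


def select_signature_genes(profiles: pd.DataFrame, target,
                           n_each: int = 3000) -> list:
    """Union of top-expressed and top-specific genes for a target trajectory.

    Ranks genes by aggregate expression in the target and by specificity
    (target expression / row sum across trajectories, 0 for all-zero genes);
    ties keep the earlier gene. Fewer than ``n_each`` genes returns all genes
    with a warning.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 trajectories")
    if target not in profiles.columns:
        raise KeyError(f"unknown trajectory {target!r}")
    if profiles.shape[0] <= n_each:
        import warnings
        warnings.warn("fewer genes than n_each; using all genes",
                      UserWarning, stacklevel=2)
        return list(profiles.index)
    expr = profiles[target].to_numpy(dtype=float)
    row_sum = profiles.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = np.where(row_sum > 0, expr / row_sum, 0.0)
    # stable sort on negated values keeps gene order among ties
    top_expr = np.argsort(-expr, kind="stable")[:n_each]
    top_spec = np.argsort(-specificity, kind="stable")[:n_each]
    keep = np.zeros(len(expr), dtype=bool)
    keep[top_expr] = True
    keep[top_spec] = True
    return list(profiles.index[keep])


def nnls_predict(target_profile, predictor_profiles) -> tuple[float, np.ndarray]:
    """Least squares with non-negative slopes and a free intercept.

    The intercept is handled by centering: slopes are fitted on mean-centered
    data so only they carry the sign constraint.
    """
    y = np.asarray(target_profile, dtype=float)
    X = np.asarray(predictor_profiles, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("gene rows of target and predictors are not aligned")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    coef, _ = nnls(X - x_mean, y - y_mean)
    intercept = y_mean - coef @ x_mean
    return float(intercept), coef


class TrajectoryMatcher(BaseEstimator):
    """Reciprocal NNLS matcher between two trajectory profile matrices.

    Fit on two genes x trajectories DataFrames sharing a gene universe;
    attributes ``beta_ab_``, ``beta_ba_``, ``combined_``, ``best_match_``.
    """

    def __init__(self, n_signature: int = 3000):
        self.n_signature = n_signature

    def fit(self, profiles_a: pd.DataFrame,
            profiles_b: pd.DataFrame) -> "TrajectoryMatcher":
        shared = profiles_a.index.intersection(profiles_b.index)
        if len(shared) == 0:
            raise ValueError("the two atlases share no genes")
        A = profiles_a.loc[shared]
        B = profiles_b.loc[shared]
        traj_a, traj_b = list(A.columns), list(B.columns)
        beta_ab = pd.DataFrame(0.0, index=traj_a, columns=traj_b)
        beta_ba = pd.DataFrame(0.0, index=traj_b, columns=traj_a)
        gene_sets: dict = {}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for a in traj_a:
                genes = select_signature_genes(A, a, self.n_signature)
                gene_sets[("a", a)] = genes
                _, coef = nnls_predict(A.loc[genes, a].to_numpy(),
                                       B.loc[genes].to_numpy())
                beta_ab.loc[a] = coef
            for b in traj_b:
                genes = select_signature_genes(B, b, self.n_signature)
                gene_sets[("b", b)] = genes
                _, coef = nnls_predict(B.loc[genes, b].to_numpy(),
                                       A.loc[genes].to_numpy())
                beta_ba.loc[b] = coef
        combined = 2.0 * (beta_ab + NNLS_OFFSET) * (beta_ba.T + NNLS_OFFSET)
        self.beta_ab_, self.beta_ba_ = beta_ab, beta_ba
        self.combined_ = combined
        self.best_match_ = combined.idxmax(axis=1)
        self.gene_sets_ = gene_sets
        return self

    def result(self) -> TrajectoryMatch:
        return TrajectoryMatch(
            trajectories_a=list(self.beta_ab_.index),
            trajectories_b=list(self.beta_ba_.index),
            beta_ab=self.beta_ab_, beta_ba=self.beta_ba_,
            combined=self.combined_, best_match=self.best_match_,
            gene_sets=self.gene_sets_)


def reciprocal_match(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                     n_signature: int = 3000) -> TrajectoryMatch:
    """Functional wrapper over :class:`TrajectoryMatcher`."""
    return TrajectoryMatcher(n_signature=n_signature).fit(
        profiles_a, profiles_b).result()
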