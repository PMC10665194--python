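"""Developmental staging by pseudobulk PCA projection.

Per-embryo pseudobulk profiles are size-factor normalized, log2-transformed
with a pseudocount of 1, and reduced by centered (unscaled) PCA. A staged
reference timecourse defines the PCA space; query embryos are projected onto
it, and on a drifting timecourse the leading component tracks developmental
age, so projected coordinates order embryos by stage.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .qc import compute_size_factors

__all__ = ["PseudobulkStagingPCA", "fit_pca_reference", "project_onto_pca",
           "normalize_log_profiles"]

log = logging.getLogger("phenoscape.staging")


def normalize_log_profiles(profiles: pd.DataFrame,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Size-factor normalize each column then log2(x + pseudocount)."""
    sf = compute_size_factors(profiles.sum(axis=0))
    return np.log2(profiles / sf.to_numpy()[None, :] + pseudocount)


class PseudobulkStagingPCA(BaseEstimator, TransformerMixin):
    """Centered PCA on normalized log pseudobulk profiles.

    Parameters
    ----------
    n_pcs
        Number of components to retain; clamped (with a warning) to the rank
        available from the training profiles.
    pseudocount
        Added before the log2 transform.

    Attributes
    ----------
    feature_ids_ : ordered gene list of the training profiles
    mean_ : per-feature center of the normalized log profiles
    components_ : (n_pcs, n_features) orthonormal rotation
    n_pcs_ : components actually retained
    """

    def __init__(self, n_pcs: int = 50, pseudocount: float = 1.0):
        self.n_pcs = n_pcs
        self.pseudocount = pseudocount

    def fit(self, profiles: pd.DataFrame, y=None) -> "PseudobulkStagingPCA":
        """Fit on a genes x samples matrix of raw pseudobulk counts."""
        profiles = self._as_frame(profiles)
        totals = profiles.sum(axis=0).to_numpy(dtype=float)
        # depth reference for projecting queries (incl. single samples)
        self.log_geomean_total_ = float(np.log(totals).mean())
        X = normalize_log_profiles(profiles, self.pseudocount).to_numpy().T
        max_rank = min(X.shape[0] - 1, X.shape[1])
        n_pcs = self.n_pcs
        if n_pcs > max_rank:
            warnings.warn(
                f"n_pcs={n_pcs} exceeds the available rank {max_rank}; "
                "clamping", UserWarning, stacklevel=2)
            n_pcs = max_rank
        pca = PCA(n_components=n_pcs, svd_solver="full")
        self.scores_ = pca.fit_transform(X)
        self.feature_ids_ = list(profiles.index)
        self.mean_ = pca.mean_
        self.components_ = pca.components_
        self.n_pcs_ = n_pcs
        return self

    def transform(self, profiles: pd.DataFrame) -> np.ndarray:
        """Project genes x samples raw pseudobulk counts onto the fitted space.

        Features missing from the query are imputed as 0 (with a warning);
        less than 50% feature overlap is rejected.
        """
        profiles = self._as_frame(profiles)
        overlap = profiles.index.intersection(self.feature_ids_)
        if len(overlap) < 0.5 * len(self.feature_ids_):
            raise ValueError(
                f"only {len(overlap)}/{len(self.feature_ids_)} model features "
                "present in the query (<50% overlap)")
        sf = profiles.sum(axis=0).to_numpy(dtype=float) / np.exp(
            self.log_geomean_total_)
        X = np.log2(profiles / sf[None, :] + self.pseudocount)
        missing = [g for g in self.feature_ids_ if g not in X.index]
        if missing:
            warnings.warn(
                f"{len(missing)} model features missing from the query; "
                "imputed as 0", UserWarning, stacklevel=2)
        X = X.reindex(self.feature_ids_, fill_value=0.0).to_numpy().T
        return (X - self.mean_) @ self.components_.T

    @staticmethod
    def _as_frame(profiles) -> pd.DataFrame:
        if not isinstance(profiles, pd.DataFrame):
            profiles = pd.DataFrame(np.asarray(profiles, dtype=float))
        return profiles


def fit_pca_reference(profiles: pd.DataFrame,
                      n_pcs: int = 50) -> PseudobulkStagingPCA:
    """Fit the staging PCA on reference pseudobulk profiles (genes x samples)."""
    return PseudobulkStagingPCA(n_pcs=n_pcs).fit(profiles)


def project_onto_pca(model: PseudobulkStagingPCA,
                     profiles: pd.DataFrame) -> np.ndarray:
    """Project query pseudobulk profiles onto a fitted staging PCA."""
    return model.transform(profiles)
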