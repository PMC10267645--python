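"""Partial least squares correlation (PLSC) of two z-scored data blocks.

Given a behavior block Y (M x N) and a brain block X (M x V), both
within-subject z-scored, the cross-product R = Y^T X is decomposed by SVD,
R = U diag(delta) W^T.  Columns of U (behavior saliences) and W (voxel
saliences) pair maximally covarying patterns; delta_k^2 / sum(delta^2) is the
fraction of cross-block covariance carried by latent variable k.  Latent
scores are the projections Lx = X W and Ly = Y U, and the decomposition
guarantees Ly^T Lx = diag(delta).

R is kept as the raw cross-product (not divided by M): the scale cancels in
saliences, covariance fractions, permutation p-values, and stability scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BehaviorMatrix, BrainMatrix

__all__ = [
    "PLSCModel",
    "cross_covariance",
    "plsc_svd",
    "covariance_explained",
    "subset_plsc",
    "fit_plsc",
]


@dataclass
class PLSCModel:
    """Result of one PLSC decomposition.

    Attributes
    ----------
    U : (N, K) behavior saliences, orthonormal columns.
    W : (V, K) voxel saliences, orthonormal columns.
    singular_values : (K,) descending, non-negative.
    covariance_explained : (K,) fractions delta_k^2 / sum(delta^2).
    Lx, Ly : (M, K) latent scores X @ W and Y @ U (None if fit from R only).
    feature_ids : behavior feature identifiers, if known.
    """

    U: np.ndarray
    W: np.ndarray
    singular_values: np.ndarray
    covariance_explained: np.ndarray
    Lx: np.ndarray | None = None
    Ly: np.ndarray | None = None
    feature_ids: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return len(self.singular_values)


def _as_array(block) -> np.ndarray:
    if isinstance(block, (BehaviorMatrix, BrainMatrix)):
        return block.values
    return np.asarray(block, dtype=float)


def cross_covariance(X, Y) -> np.ndarray:
    """R = Y^T X for row-aligned blocks (N x V)."""
    Xa, Ya = _as_array(X), _as_array(Y)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError(
            f"row mismatch: X has {Xa.shape[0]} observations, Y has {Ya.shape[0]}"
        )
    return Ya.T @ Xa


def _sign_fix(U: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the largest-|u| element of each behavior
    salience is made positive; the paired voxel salience flips with it."""
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip, W * flip


def covariance_explained(singular_values: np.ndarray) -> np.ndarray:
    """delta_k^2 / sum_j delta_j^2."""
    d2 = np.asarray(singular_values, dtype=float) ** 2
    total = d2.sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return d2 / total


def plsc_svd(R: np.ndarray, X=None, Y=None) -> PLSCModel:
    """SVD of a cross-product matrix R (N x V) into a PLSCModel.

    When ``X`` and ``Y`` are given, latent scores are filled in.
    """
    R = np.asarray(R, dtype=float)
    U, d, Wt = np.linalg.svd(R, full_matrices=False)
    U, W = _sign_fix(U, Wt.T)
    feature_ids: tuple[str, ...] = ()
    if isinstance(Y, BehaviorMatrix):
        feature_ids = Y.feature_ids
    Lx = _as_array(X) @ W if X is not None else None
    Ly = _as_array(Y) @ U if Y is not None else None
    return PLSCModel(
        U=U,
        W=W,
        singular_values=d,
        covariance_explained=covariance_explained(d),
        Lx=Lx,
        Ly=Ly,
        feature_ids=feature_ids,
    )


def fit_plsc(X, Y) -> PLSCModel:
    """cross_covariance + plsc_svd in one call."""
    return plsc_svd(cross_covariance(X, Y), X=X, Y=Y)


def subset_plsc(X, Y: BehaviorMatrix, feature_subset) -> PLSCModel:
    """PLSC with the behavior block restricted to ``feature_subset`` columns.

    Columns are reused as prepared (already within-subject z-scored);
    restricting columns does not change their normalization.
    """
    Ysub = Y.subset_features(list(feature_subset))
    return fit_plsc(X, Ysub)
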