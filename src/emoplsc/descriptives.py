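"""Descriptive analyses: centroid clustering, factor analysis, LV profiles.

Covers the supporting analyses around the PLSC model: Ward hierarchical
clustering of discrete-emotion centroid profiles (squared Euclidean
distances), exploratory factor analysis of the 34-feature space (factor
count by the Kaiser criterion, minres extraction, varimax rotation),
bootstrap significance of factor loadings, Pearson correlation of emotion
centroids with LV behavior saliences, and a one-way ANOVA with eta-squared
effect size for physiology differences across emotion categories.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.linalg import orthogonal_procrustes

from .behavior import EmotionCentroids
from .plsc import PLSCModel

__all__ = [
    "ClusterTree",
    "ward_cluster",
    "kaiser_count",
    "FactorSolution",
    "efa_varimax",
    "varimax",
    "loading_significance",
    "lv_emotion_correlation",
    "AnovaResult",
    "anova_eta_squared",
    "rating_histograms",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterTree:
    """Agglomerative merge tree over emotion centroids (Ward linkage).

    ``merges`` lists 9 merges for 10 leaves as (cluster_a, cluster_b,
    height, size); indices < n_leaves are leaves, >= n_leaves are merged
    clusters in creation order (scipy linkage convention).
    """

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = self.n_leaves
        Z = self.linkage_matrix

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.labels[i]}:{parent_h:.6g}"
            row = Z[i - n]
            h = row[2]
            left = node(int(row[0]), h)
            right = node(int(row[1]), h)
            return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

        top = Z[-1, 2]
        return node(2 * n - 2, top) + ";"

    def to_nested(self) -> dict:
        """Nested-dict (JSON-ready) representation of the tree."""
        n = self.n_leaves
        Z = self.linkage_matrix

        def node(i: int) -> dict:
            if i < n:
                return {"label": self.labels[i]}
            row = Z[i - n]
            return {
                "height": float(row[2]),
                "children": [node(int(row[0])), node(int(row[1]))],
            }

        return node(2 * n - 2)

    def to_json(self) -> str:
        return json.dumps(self.to_nested())

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assign = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}


def ward_cluster(centroids: EmotionCentroids) -> ClusterTree:
    """Ward agglomeration of emotion centroid profiles.

    Ward's objective merges the pair of clusters with the smallest increase
    in within-cluster sum of squared Euclidean distances.  Categories with
    no observations are excluded (they have no profile).
    """
    keep = [
        i for i, cat in enumerate(centroids.categories)
        if cat not in centroids.empty_categories
    ]
    X = centroids.values[keep]
    labels = tuple(centroids.categories[i] for i in keep)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty categories to cluster")
    Z = linkage(X, method="ward")
    return ClusterTree(linkage_matrix=Z, labels=labels)


# ---------------------------------------------------------------------------
# exploratory factor analysis


def kaiser_count(feature_matrix: np.ndarray) -> int:
    """Number of correlation-matrix eigenvalues strictly greater than 1."""
    X = np.asarray(feature_matrix, dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)
    # strictly greater than 1, with a guard for eigenvalues that are exactly
    # 1 up to floating-point noise (e.g. perfectly uncorrelated features)
    return int((eig > 1.0 + 1e-9).sum())


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """Orthogonal varimax rotation (Kaiser, normalized criterion not applied).

    Iteratively maximizes the sum over factors of the variance of squared
    loadings.  Returns (rotated loadings, rotation matrix); the criterion is
    non-decreasing across sweeps.
    """
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        tmp = Lr**3 - Lr * (Lr**2).sum(axis=0) / n
        u, s, vt = np.linalg.svd(L.T @ tmp)
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R, R


def _minres_extract(corr: np.ndarray, n_factors: int) -> np.ndarray:
    """Minimum-residual factor extraction.

    Finds communalities minimizing the squared off-diagonal residuals of the
    reproduced correlation matrix; loadings come from the top eigenpairs of
    the reduced matrix.
    """
    from scipy.optimize import minimize

    p = corr.shape[0]

    def loadings_for(psi: np.ndarray) -> np.ndarray:
        reduced = corr - np.diag(psi)
        eigval, eigvec = np.linalg.eigh(reduced)
        idx = np.argsort(eigval)[::-1][:n_factors]
        lam = np.sqrt(np.maximum(eigval[idx], 0.0))
        return eigvec[:, idx] * lam

    def objective(psi: np.ndarray) -> float:
        L = loadings_for(psi)
        resid = corr - L @ L.T
        np.fill_diagonal(resid, 0.0)
        return float((resid**2).sum())

    # start from squared multiple correlations
    inv = np.linalg.pinv(corr)
    smc = 1.0 - 1.0 / np.clip(np.diag(inv), 1.0, None)
    x0 = np.clip(1.0 - smc, 0.005, 0.995)
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        options={"maxiter": 1000},
    )
    return loadings_for(res.x)


def _principal_axis_extract(corr: np.ndarray, n_factors: int, n_iter: int = 50) -> np.ndarray:
    """Iterated principal-axis factoring (communality iteration)."""
    h2 = 1.0 - 1.0 / np.clip(np.diag(np.linalg.pinv(corr)), 1.0, None)
    for _ in range(n_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        eigval, eigvec = np.linalg.eigh(reduced)
        idx = np.argsort(eigval)[::-1][:n_factors]
        L = eigvec[:, idx] * np.sqrt(np.maximum(eigval[idx], 0.0))
        h2_new = (L**2).sum(axis=1)
        if np.max(np.abs(h2_new - h2)) < 1e-8:
            h2 = h2_new
            break
        h2 = h2_new
    reduced = corr.copy()
    np.fill_diagonal(reduced, h2)
    eigval, eigvec = np.linalg.eigh(reduced)
    idx = np.argsort(eigval)[::-1][:n_factors]
    return eigvec[:, idx] * np.sqrt(np.maximum(eigval[idx], 0.0))


@dataclass
class FactorSolution:
    """Varimax-rotated factor loading matrix with variance accounting."""

    loadings: np.ndarray              # N x F
    rotation: np.ndarray              # F x F orthogonal
    variance_explained: np.ndarray    # F, fraction of total variance
    feature_ids: tuple[str, ...]
    method: str
    significant: np.ndarray | None = None

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def total_variance_explained(self) -> float:
        return float(self.variance_explained.sum())

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"D{j + 1}" for j in range(self.n_factors)]
        return pd.DataFrame(self.loadings, index=list(self.feature_ids), columns=cols)


def _smooth_corr(corr: np.ndarray) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() > 1e-10:
        return corr
    warnings.warn("correlation matrix not positive definite: smoothing", RuntimeWarning)
    eigval = np.clip(eigval, 1e-8, None)
    fixed = eigvec @ np.diag(eigval) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def efa_varimax(
    feature_matrix: np.ndarray,
    n_factors: int,
    feature_ids: tuple[str, ...] | None = None,
    method: str = "minres",
) -> FactorSolution:
    """Exploratory factor analysis with varimax rotation.

    Factors are extracted from the feature correlation matrix (``minres`` by
    default, ``principal_axis`` as an option), varimax-rotated, ordered by
    explained variance, and sign-fixed so the largest-|loading| entry of each
    factor is positive.
    """
    X = np.asarray(feature_matrix, dtype=float)
    n_obs, p = X.shape
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be in [1, n_features)")
    corr = _smooth_corr(np.corrcoef(X, rowvar=False))
    if method == "minres":
        L = _minres_extract(corr, n_factors)
    elif method == "principal_axis":
        L = _principal_axis_extract(corr, n_factors)
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    L_rot, R = varimax(L)

    var_per_factor = (L_rot**2).sum(axis=0) / p
    order = np.argsort(var_per_factor)[::-1]
    L_rot = L_rot[:, order]
    R = R[:, order]
    var_per_factor = var_per_factor[order]
    flip = np.sign(L_rot[np.abs(L_rot).argmax(axis=0), np.arange(n_factors)])
    flip[flip == 0] = 1.0
    L_rot = L_rot * flip
    R = R * flip

    if feature_ids is None:
        feature_ids = tuple(f"feature_{i:02d}" for i in range(p))
    return FactorSolution(
        loadings=L_rot,
        rotation=R,
        variance_explained=var_per_factor,
        feature_ids=tuple(feature_ids),
        method=method,
    )


def loading_significance(
    feature_matrix: np.ndarray,
    solution: FactorSolution,
    subjects: np.ndarray,
    n_boot: int = 200,
    alpha: float = 0.05,
    method: str | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Bootstrap significance flags for factor loadings.

    Subjects are resampled with replacement; each resampled solution is
    Procrustes-aligned to the full-sample loadings; a loading is flagged when
    its two-sided bootstrap percentile interval excludes zero at ``alpha``.
    """
    X = np.asarray(feature_matrix, dtype=float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    rows_of = {s: np.flatnonzero(subjects == s) for s in uniq}
    method = method or solution.method
    boots = np.empty((n_boot,) + solution.loadings.shape)
    for b in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        rows = np.concatenate([rows_of[s] for s in chosen])
        sol_b = efa_varimax(
            X[rows], solution.n_factors, solution.feature_ids, method=method
        )
        Q, _ = orthogonal_procrustes(sol_b.loadings, solution.loadings)
        boots[b] = sol_b.loadings @ Q
    lo = np.quantile(boots, alpha / 2, axis=0)
    hi = np.quantile(boots, 1 - alpha / 2, axis=0)
    return (lo > 0) | (hi < 0)


# ---------------------------------------------------------------------------
# LV-emotion correlation, ANOVA, histograms


def lv_emotion_correlation(
    model: PLSCModel, centroids: EmotionCentroids, n_components: int | None = None
) -> pd.DataFrame:
    """Pearson correlation (over features) between each emotion centroid
    profile and each LV behavior-salience vector (categories x K)."""
    K = model.n_components if n_components is None else n_components
    U = model.U[:, :K]
    if U.shape[0] != centroids.values.shape[1]:
        raise ValueError("feature dimensions of model and centroids differ")
    out = np.empty((len(centroids.categories), K))
    for i, profile in enumerate(centroids.values):
        for k in range(K):
            out[i, k] = np.corrcoef(profile, U[:, k])[0, 1]
    return pd.DataFrame(
        out,
        index=list(centroids.categories),
        columns=[f"LV{k + 1}" for k in range(K)],
    )


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA with eta-squared effect size."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float


def anova_eta_squared(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """One-way ANOVA of ``values`` across ``groups``; eta^2 = SS_b / SS_t."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_between = sum(
        len(v := values[groups == g]) * (v.mean() - grand) ** 2 for g in uniq
    )
    df_b = len(uniq) - 1
    df_w = len(values) - len(uniq)
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return AnovaResult(
        F=float(F), df_between=df_b, df_within=df_w, p_value=p, eta_squared=eta2
    )


def rating_histograms(ratings: pd.DataFrame, feature_ids, levels=range(1, 8)):
    """Per-feature counts over Likert levels and per-label event counts.

    Returns ``(histograms, label_counts, skewness)``: a features x levels
    count table (continuous ratings are rounded and clipped into the level
    range for binning), the primary-emotion label counts, and per-feature
    skewness.
    """
    levels = list(levels)
    counts = pd.DataFrame(0, index=list(feature_ids), columns=levels, dtype=int)
    skew = {}
    for fid in feature_ids:
        col = ratings[fid].to_numpy(dtype=float)
        binned = np.clip(np.rint(col), levels[0], levels[-1]).astype(int)
        for lev in levels:
            counts.loc[fid, lev] = int((binned == lev).sum())
        skew[fid] = float(stats.skew(col))
    label_counts = (
        ratings["primary_emotion"].value_counts().sort_index()
        if "primary_emotion" in ratings.columns
        else pd.Series(dtype=int)
    )
    return counts, label_counts, pd.Series(skew)
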