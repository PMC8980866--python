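"""Temporal and sample-level clustering.

Fuzzy c-means (Bezdek alternating optimization) clusters per-item
standardized stage profiles so clusters capture shape rather than
abundance; a membership threshold turns soft memberships into hard
assignments, leaving low-confidence items unassigned. Ward hierarchical
clustering uses the classic Lance-Williams Ward update applied to plain
Euclidean distances (the "ward.D" behavior, not the squared-distance
"ward.D2" variant). PCA scores and Pearson sample-correlation matrices
summarize replicate reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import cdist, pdist

from ripeomics.io_formats import ExpressionMatrix

__all__ = [
    "FcmResult",
    "DendrogramResult",
    "standardize_profiles",
    "fuzzy_cmeans",
    "assign_fuzzy_clusters",
    "ward_hierarchical",
    "pca_scores",
    "sample_correlation_matrix",
]


def standardize_profiles(
    profiles: pd.DataFrame, min_sd: float = 1e-12
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each row across its columns; rows with ~zero variance are dropped.

    Returns the standardized frame and the list of excluded item IDs.
    """
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > min_sd
    excluded = list(profiles.index[~keep])
    if excluded:
        warnings.warn(
            f"{len(excluded)} zero-variance item(s) excluded from clustering", stacklevel=2
        )
    z = (x[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=profiles.index[keep], columns=profiles.columns), excluded


@dataclass
class FcmResult:
    centers: pd.DataFrame  # c x features
    membership: pd.DataFrame  # items x c, rows sum to 1
    fuzzifier: float
    objective_trace: list[float]
    excluded: list[str]

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    standardize: bool = True,
) -> FcmResult:
    """Fuzzy c-means clustering of item x feature profiles.

    Standard Bezdek alternating updates of the membership matrix and the
    cluster centers, iterated until the objective improves by less than
    ``tol``. Memberships are initialized from a symmetric Dirichlet with
    the given seed, so runs are deterministic.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    excluded: list[str] = []
    if standardize:
        profiles, excluded = standardize_profiles(profiles)
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds number of items ({n})")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(c), size=n)  # n x c
    trace: list[float] = []
    exponent = 2.0 / (m - 1.0)
    centers = np.zeros((c, X.shape[1]))
    for _ in range(max_iter):
        W = U**m
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = cdist(X, centers, metric="sqeuclidean")
        trace.append(float((W * d2).sum()))
        # membership update; exact-hit rows get membership 1 on the nearest center
        zero = d2 <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))  # d^{-2/(m-1)} on squared distances
            U = inv / inv.sum(axis=1, keepdims=True)
        hit_rows = zero.any(axis=1)
        if hit_rows.any():
            U[hit_rows] = 0.0
            first_hit = np.argmax(zero[hit_rows], axis=1)
            U[np.flatnonzero(hit_rows), first_hit] = 1.0
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < tol:
            break
    W = U**m
    d2 = cdist(X, centers, metric="sqeuclidean")
    trace.append(float((W * d2).sum()))
    cluster_ids = [f"C{i + 1}" for i in range(c)]
    return FcmResult(
        centers=pd.DataFrame(centers, index=cluster_ids, columns=profiles.columns),
        membership=pd.DataFrame(U, index=profiles.index, columns=cluster_ids),
        fuzzifier=m,
        objective_trace=trace,
        excluded=excluded,
    )


def assign_fuzzy_clusters(result: FcmResult, tau: float = 0.5) -> pd.Series:
    """Hard assignment: argmax cluster when max membership > tau, else unassigned.

    Argmax ties break toward the lowest cluster index. ``tau`` must lie in
    (1/c, 1].
    """
    c = result.n_clusters
    if not (1.0 / c <= tau <= 1.0):
        raise ValueError(f"tau must lie in [1/{c}, 1], got {tau}")
    U = result.membership.to_numpy()
    best = U.argmax(axis=1)
    labels = np.where(
        U[np.arange(len(best)), best] > tau,
        result.membership.columns.to_numpy()[best],
        "unassigned",
    )
    return pd.Series(labels, index=result.membership.index, name="cluster")


@dataclass
class DendrogramResult:
    merges: np.ndarray  # (n-1) x 2 merged node indices, scipy convention
    heights: np.ndarray  # (n-1,) merge criterion values, non-decreasing
    leaf_order: list[str]
    assignments: pd.Series  # item -> cluster id 1..k for the requested cut
    k: int


def ward_hierarchical(profiles: pd.DataFrame, k: int) -> DendrogramResult:
    """Ward minimum-variance clustering with the classic "ward.D" update.

    The Lance-Williams Ward recurrence is applied to plain Euclidean
    distances. Internally this runs scipy's Ward linkage on the square
    roots of the pairwise distances (scipy's recurrence operates on
    squared inputs), which reproduces the same merge sequence; reported
    heights are squared back onto the plain-distance criterion scale.
    """
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of items ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = pdist(profiles.to_numpy(dtype=float), metric="euclidean")
    Z = linkage(np.sqrt(d), method="ward")
    heights = Z[:, 2] ** 2
    labels = fcluster(Z, t=k, criterion="maxclust")
    leaf_order = [profiles.index[i] for i in leaves_list(Z)]
    return DendrogramResult(
        merges=Z[:, :2].astype(int),
        heights=heights,
        leaf_order=leaf_order,
        assignments=pd.Series(labels, index=profiles.index, name="cluster"),
        k=k,
    )


def pca_scores(
    matrix: ExpressionMatrix, scale: bool = False, log2: bool = True, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA via SVD of the centered sample x feature matrix.

    Returns ``(scores, variance_fractions)``; scores rows are samples.
    Features are optionally unit-variance scaled; constant features are
    dropped when scaling.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if log2:
        X = np.log2(X + pseudocount)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X[:, sd > 0] / sd[sd > 0]
    if not np.any(X != 0):
        raise ValueError("constant matrix; PCA undefined")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    var_frac = S**2 / (S**2).sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.values.columns, columns=cols), var_frac


def sample_correlation_matrix(
    matrix: ExpressionMatrix, log2: bool = True, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Pearson correlation between samples, on log2(value + 1) by default.

    Zero-variance samples yield NaN rows/columns with a warning; the
    diagonal is exactly 1 for well-defined samples.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 features")
    if log2:
        X = np.log2(X + pseudocount)
    bad = np.ptp(X, axis=0) == 0  # exactly constant columns
    if bad.any():
        warnings.warn(
            f"zero-variance sample(s): {list(matrix.values.columns[bad])}", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = (corr + corr.T) / 2.0  # force exact symmetry (BLAS ulp drift)
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    diag = np.where(bad, np.nan, 1.0)
    corr[np.diag_indices_from(corr)] = diag  # exact unit diagonal for defined samples
    return pd.DataFrame(corr, index=matrix.values.columns, columns=matrix.values.columns)
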