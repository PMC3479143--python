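"""Initialization strategies for the NMF factorizers.

Six strategies are provided: uniform random, K-means, fuzzy c-means
(FCM), PCA, ICA, and a short warm run of multiplicative-update NMF
itself.  Each returns non-negative starting factors ``(W0, H0)`` and,
for the convex variant, the auxiliary weight matrix ``G0`` with
``W0 = X @ G0`` holding exactly (the convex variant constrains sources
to the column space of the data).

The K-means construction for the convex path follows the cluster-
indicator recipe: ``H0 = B + 0.2*E`` where ``B`` is the binary k x n
cluster-indicator matrix and ``E`` is all ones, and
``G0 = B^T D^{-1} + 0.2*E`` with ``D = diag(cluster sizes)``.  The same
0.2 smoothing offset is reused for FCM memberships.

All strategies are deterministic given ``(X, k, seed)``.  Callers pass
the matrix that will actually be factorized: the magnitude-transformed
data for the non-negative variants, the raw mixed-sign data for the
convex variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA

OFFSET = 0.2  # smoothing added to cluster-indicator initial matrices


class InitKind(str, Enum):
    RANDOM = "random"
    KMEANS = "kmeans"
    FCM = "fcm"
    PCA = "pca"
    ICA = "ica"
    NMF = "nmf"


@dataclass(frozen=True)
class InitStrategy:
    kind: InitKind = InitKind.KMEANS
    seed: int = 0
    fcm_m: float = 2.0
    nmf_warm_iters: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", InitKind(self.kind))


@dataclass
class InitResult:
    """Starting factors; ``G0`` is present only for the convex path."""

    W0: np.ndarray
    H0: np.ndarray
    G0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.H0 = np.asarray(self.H0, dtype=float)
        if np.any(self.H0 < 0):
            raise ValueError("H0 must be non-negative")
        if self.G0 is not None:
            self.G0 = np.asarray(self.G0, dtype=float)
            if np.any(self.G0 < 0):
                raise ValueError("G0 must be non-negative")


def _check_k(X: np.ndarray, k: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= X.shape[1]:
        raise ValueError(f"k={k} must be smaller than the number of voxels n={X.shape[1]}")


def init_random(X: np.ndarray, k: int, seed: int, convex: bool = False) -> InitResult:
    """All initialized entries uniform in (0, 1); convex path draws G0
    and sets W0 = X @ G0."""
    X = np.asarray(X, dtype=float)
    _check_k(X, k)
    rng = np.random.default_rng(seed)
    p, n = X.shape
    H0 = rng.uniform(size=(k, n))
    if convex:
        G0 = rng.uniform(size=(n, k))
        return InitResult(W0=X @ G0, H0=H0, G0=G0)
    return InitResult(W0=rng.uniform(size=(p, k)), H0=H0)


def _kmeans_indicator(X: np.ndarray, k: int, seed: int, attempts: int = 5):
    """Cluster the n voxel spectra; return (B, centroids) with B the
    binary k x n indicator.  Empty clusters trigger a bounded re-seed."""
    n = X.shape[1]
    if n < k:
        raise ValueError("need at least k voxels to run K-means")
    for attempt in range(attempts):
        km = KMeans(n_clusters=k, random_state=seed + attempt, n_init=10)
        assign = km.fit_predict(X.T)
        sizes = np.bincount(assign, minlength=k)
        if np.all(sizes > 0):
            B = np.zeros((k, n))
            B[assign, np.arange(n)] = 1.0
            return B, km.cluster_centers_.T
    raise RuntimeError(f"K-means produced an empty cluster in {attempts} attempts")


def init_kmeans(X: np.ndarray, k: int, seed: int, convex: bool = False) -> InitResult:
    X = np.asarray(X, dtype=float)
    _check_k(X, k)
    B, centroids = _kmeans_indicator(X, k, seed)
    H0 = B + OFFSET
    if convex:
        D_inv = 1.0 / B.sum(axis=1)  # cluster sizes, all > 0 by construction
        G0 = B.T * D_inv[None, :] + OFFSET
        return InitResult(W0=X @ G0, H0=H0, G0=G0)
    return InitResult(W0=centroids, H0=H0)


def _fcm(X: np.ndarray, k: int, seed: int, m: float, max_iter: int = 300,
         tol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means over the voxel spectra (columns of X).

    Standard alternating updates: centroids are membership^m-weighted
    means; memberships follow the inverse-distance rule with fuzzifier m.
    Returns (U, C): U is k x n with columns summing to 1, C is p x k.
    """
    if m <= 1:
        raise ValueError("FCM fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    U = rng.uniform(size=(k, n))
    U /= U.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        Um = U**m
        C = (X @ Um.T) / Um.sum(axis=1)[None, :]
        # squared distances voxel<->centroid, floored to avoid 0-division
        d2 = np.maximum(
            ((X[:, None, :] - C[:, :, None]) ** 2).sum(axis=0), 1e-300
        )  # k x n
        U_new = d2 ** (-1.0 / (m - 1.0))
        U_new /= U_new.sum(axis=0, keepdims=True)
        if np.max(np.abs(U_new - U)) < tol:
            return U_new, (X @ (U_new**m).T) / (U_new**m).sum(axis=1)[None, :]
        U = U_new
    raise RuntimeError(f"FCM did not converge within {max_iter} iterations")


def init_fcm(X: np.ndarray, k: int, seed: int, m: float = 2.0, convex: bool = False) -> InitResult:
    X = np.asarray(X, dtype=float)
    _check_k(X, k)
    U, C = _fcm(X, k, seed, m)
    H0 = U
    if convex:
        D_inv = 1.0 / U.sum(axis=1)
        G0 = U.T * D_inv[None, :] + OFFSET
        return InitResult(W0=X @ G0, H0=H0, G0=G0)
    return InitResult(W0=C, H0=H0)


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise non-negative least squares: argmin_{Z>=0} ||A Z - B||."""
    Z = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        Z[:, j], _ = nnls(A, B[:, j])
    return Z


def _eigen_init(W0: np.ndarray, X: np.ndarray, convex: bool) -> InitResult:
    """Shared PCA/ICA tail: make the start feasible.

    The mixed-sign components are rectified by absolute value; H0 is the
    NNLS projection of the data onto them.  The convex path solves
    W0 ~ X G0 by NNLS and resets W0 = X G0 so the column-space constraint
    holds exactly.
    """
    H0 = _nnls_columns(W0, np.abs(X))
    if convex:
        G0 = _nnls_columns(X, W0)
        return InitResult(W0=X @ G0, H0=H0, G0=G0)
    return InitResult(W0=W0, H0=H0)


def init_pca(X: np.ndarray, k: int, convex: bool = False) -> InitResult:
    """Principal axes over the spectral dimension, rectified to W0 >= 0."""
    X = np.asarray(X, dtype=float)
    _check_k(X, k)
    if k > min(X.shape):
        raise ValueError("k exceeds the data dimensions")
    centered = X - X.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(centered) < k:
        raise ValueError("k exceeds the numerical rank of the (centered) data")
    pca = PCA(n_components=k)
    pca.fit(X.T)  # samples = voxels, features = spectral points
    W0 = np.abs(pca.components_.T)
    return _eigen_init(W0, X, convex)


def init_ica(X: np.ndarray, k: int, seed: int, convex: bool = False) -> InitResult:
    """Independent components over the spectral dimension, rectified."""
    X = np.asarray(X, dtype=float)
    _check_k(X, k)
    if k > min(X.shape):
        raise ValueError("k exceeds the data dimensions")
    ica = FastICA(n_components=k, random_state=seed, max_iter=1000, whiten="unit-variance")
    ica.fit(X.T)
    W0 = np.abs(ica.components_.T)
    return _eigen_init(W0, X, convex)


def init_nmf(X: np.ndarray, k: int, seed: int, warm_iters: int = 20,
             convex: bool = False) -> InitResult:
    """Warm start: a few multiplicative-update iterations from a random
    start on the magnitude data."""
    from .nmf import FactorizationConfig, Method, factorize  # circular at import time

    X = np.asarray(X, dtype=float)
    _check_k(X, k)
    if warm_iters < 1:
        raise ValueError("warm_iters must be >= 1")
    Xm = np.abs(X)
    warm = factorize(
        Xm,
        FactorizationConfig(method=Method.EUC, k=k, max_iter=warm_iters, tol=0.0),
        init_random(Xm, k, seed),
    )
    if convex:
        G0 = _nnls_columns(X, warm.W)
        return InitResult(W0=X @ G0, H0=warm.H, G0=G0)
    return InitResult(W0=warm.W, H0=warm.H)


def initialize(X: np.ndarray, k: int, strategy: InitStrategy, convex: bool = False) -> InitResult:
    """Dispatch on the strategy kind."""
    kind = InitKind(strategy.kind)
    if kind is InitKind.RANDOM:
        return init_random(X, k, strategy.seed, convex)
    if kind is InitKind.KMEANS:
        return init_kmeans(X, k, strategy.seed, convex)
    if kind is InitKind.FCM:
        return init_fcm(X, k, strategy.seed, strategy.fcm_m, convex)
    if kind is InitKind.PCA:
        return init_pca(X, k, convex)
    if kind is InitKind.ICA:
        return init_ica(X, k, strategy.seed, convex)
    return init_nmf(X, k, strategy.seed, strategy.nmf_warm_iters, convex)
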