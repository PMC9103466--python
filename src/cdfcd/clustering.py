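"""Clustering stage: linkage, normalized spectral, and PCA subspace clustering.

Spectral clustering builds a Gaussian-kernel weight matrix
``W_ij = exp(-d(x_i,x_j)^2 / (2 sigma^2))``, forms the symmetric normalized
Laplacian ``L_sym = I - D^{-1/2} W D^{-1/2}``, estimates the cluster count
from the largest eigengap, row-normalizes the K principal eigenvectors and
runs K-means on the embedding.

PCA subspace clustering samples anchor points, fits a local PCA subspace to
each anchor's neighborhood, scores anchor pairs by the alignment of their
principal subspaces (mean squared cosine of principal angles), sparsifies and
symmetrizes the affinity, spectral-clusters the anchors and labels the
remaining points by nearest anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from .datamodel import EpochMatrix


@dataclass
class WeightMatrix:
    W: np.ndarray
    sigma: float
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if (W < -1e-12).any() or (W > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(W, 0.0)
        self.W = W


@dataclass
class LaplacianBundle:
    L_sym: np.ndarray
    degrees: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    K: int
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=self.K)
        if (sizes == 0).any():
            raise ValueError("every cluster must be non-empty")

    @classmethod
    def from_labels(cls, labels: np.ndarray, X: np.ndarray) -> "ClusterAssignment":
        labels = np.asarray(labels, dtype=int)
        K = labels.max() + 1
        cents = np.stack([X[labels == k].mean(axis=0) for k in range(K)])
        return cls(labels, K, cents)


def _as_array(X) -> np.ndarray:
    return X.X if isinstance(X, EpochMatrix) else np.asarray(X, dtype=float)


def linkage_dissimilarity(Ci: np.ndarray, Cj: np.ndarray, mode: str = "single") -> float:
    """Single/complete linkage dissimilarity between two point sets.

    Single linkage is the minimum cross-pair Euclidean distance, complete
    linkage the maximum.
    """
    Ci, Cj = np.atleast_2d(Ci), np.atleast_2d(Cj)
    if Ci.size == 0 or Cj.size == 0:
        raise ValueError("linkage between empty clusters is undefined")
    D = cdist(Ci, Cj)
    if mode == "single":
        return float(D.min())
    if mode == "complete":
        return float(D.max())
    raise ValueError(f"unknown linkage mode: {mode}")


def hierarchical_cluster(X, K: int, mode: str = "single") -> ClusterAssignment:
    """Agglomerative clustering merging the closest pair until K clusters remain."""
    A = _as_array(X)
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > A.shape[0]:
        raise ValueError("K cannot exceed the number of rows")
    if K == A.shape[0]:
        labels = np.arange(A.shape[0])
    else:
        Z = linkage(A, method=mode, metric="euclidean")
        labels = fcluster(Z, t=K, criterion="maxclust") - 1
    # relabel by first occurrence for determinism
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterAssignment.from_labels(labels, A)


def build_weight_matrix(X, sigma: float | str = "auto") -> WeightMatrix:
    """Gaussian-kernel weights with Euclidean distances and zero diagonal.

    ``sigma='auto'`` uses a local scale (median distance to the 7th nearest
    neighbor), which keeps between-cluster weights small however far apart
    the clusters sit; ``sigma='median'`` uses the global median pairwise
    distance.  All-identical rows make either scale degenerate and raise.
    """
    A = _as_array(X)
    d = pdist(A)
    if sigma == "median":
        sigma = float(np.median(d))
        if sigma <= 0:
            raise ValueError("median sigma degenerate: all rows identical")
    elif sigma == "auto":
        # local scale: median distance to the k-th nearest neighbor; a global
        # median pairwise distance grows with between-cluster separation and
        # washes out the eigengap
        D = squareform(d)
        k = min(7, A.shape[0] - 1)
        kth = np.sort(D, axis=1)[:, k]
        sigma = float(np.median(kth))
        if sigma <= 0:
            sigma = float(np.median(d))
        if sigma <= 0:
            raise ValueError("auto sigma degenerate: all rows identical")
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    W = np.exp(-squareform(d) ** 2 / (2.0 * sigma**2))
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, sigma)


def symmetric_laplacian(wm: WeightMatrix) -> LaplacianBundle:
    """Form ``L_sym = I - D^{-1/2} W D^{-1/2}`` and its sorted eigensystem."""
    W = wm.W
    deg = W.sum(axis=1)
    zero = np.flatnonzero(deg <= 0)
    if zero.size:
        raise ValueError(f"isolated node(s) with zero degree: {zero.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(deg)) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = 0.5 * (L + L.T)
    eigvals, eigvecs = np.linalg.eigh(L)
    return LaplacianBundle(L, deg, eigvals, eigvecs)


def estimate_num_clusters(eigvals: np.ndarray, max_k: int = 50) -> int:
    """Largest-eigengap estimate of the cluster count.

    Returns the 1-based index ``i`` maximizing ``lambda_{i+1} - lambda_i``;
    the first maximal gap wins ties.  The search is restricted to the first
    ``min(n-1, max_k)`` gaps to avoid trailing-spectrum artifacts.
    """
    lam = np.asarray(eigvals, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least two eigenvalues")
    gaps = np.diff(lam)[: min(lam.size - 1, max_k)]
    return int(np.argmax(gaps)) + 1


def spectral_embed(bundle: LaplacianBundle, K: int) -> np.ndarray:
    """Row-normalized embedding on the K principal (smallest-eigenvalue) eigenvectors."""
    Phi = bundle.eigvecs[:, :K]
    norms = np.linalg.norm(Phi, axis=1)
    V = np.zeros_like(Phi)
    ok = norms >= 1e-12
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} embedding row(s) with near-zero norm set to zero")
    V[ok] = Phi[ok] / norms[ok, None]
    return V


def spectral_cluster(
    X, sigma: float | str = "auto", K: int | str = "auto", seed: int = 0
) -> ClusterAssignment:
    """Normalized spectral clustering with eigengap model selection.

    ``X`` may be raw data (rows are points) or a precomputed
    :class:`WeightMatrix`.
    """
    if isinstance(X, WeightMatrix):
        if X.W.shape[0] < 2:
            raise ValueError("need at least two rows")
        return _spectral_cluster_from_weights(X, K, seed)
    A = _as_array(X)
    if A.shape[0] < 2:
        raise ValueError("need at least two rows")
    wm = build_weight_matrix(A, sigma)
    return _spectral_cluster_from_weights(wm, K, seed, centroids_in=A)


def _spectral_cluster_from_weights(
    wm: WeightMatrix, K: int | str, seed: int, centroids_in: np.ndarray | None = None
) -> ClusterAssignment:
    bundle = symmetric_laplacian(wm)
    k = estimate_num_clusters(bundle.eigvals) if K == "auto" else int(K)
    V = spectral_embed(bundle, k)
    if k == wm.W.shape[0]:
        labels = np.arange(k)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(V)
    _, labels = np.unique(labels, return_inverse=True)
    space = V if centroids_in is None else centroids_in
    return ClusterAssignment.from_labels(labels, space)


def _principal_subspace(P: np.ndarray, dmax: int, var_frac: float = 0.90) -> np.ndarray:
    """Orthonormal basis of the local PCA subspace capturing >=90% variance, rank <= dmax."""
    C = P - P.mean(axis=0)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        return Vt[:1].T
    cum = np.cumsum(var) / total
    rank = int(np.searchsorted(cum, var_frac) + 1)
    rank = min(rank, dmax, Vt.shape[0])
    return Vt[:rank].T


def _subspace_affinity(B1: np.ndarray, B2: np.ndarray) -> float:
    """Mean squared cosine of principal angles between two subspaces, in [0, 1]."""
    s = np.linalg.svd(B1.T @ B2, compute_uv=False)
    d = min(B1.shape[1], B2.shape[1])
    return float(np.sum(np.clip(s, 0, 1) ** 2) / d)


def pca_subspace_cluster(
    X,
    k: int,
    n_sample: int | None = None,
    dmax: int = 5,
    t_max: float | None = None,
    seed: int = 0,
    lambda1: float | None = None,
    lambda2: float | None = None,
    m: int | None = None,
) -> np.ndarray:
    """PCA-based subspace clustering; returns labels for all rows.

    Anchors are a uniform sample of ``n_sample`` rows; each anchor's
    subcluster is its ``dmax + 1`` nearest neighbors in the full data.  The
    regularization/threshold parameters ``lambda1``, ``lambda2``, ``m`` and
    ``t_max`` are accepted for interface compatibility but unused by the
    procedure; passing them warns.
    """
    if any(v is not None for v in (lambda1, lambda2, m, t_max)):
        warnings.warn("lambda1/lambda2/m/t_max are accepted but unused")
    A = _as_array(X)
    n = A.shape[0]
    n_sample = n if n_sample is None else int(n_sample)
    if n_sample > n:
        raise ValueError("n_sample cannot exceed the number of rows")
    if k > n_sample:
        raise ValueError("k cannot exceed n_sample")
    if dmax < 1:
        raise ValueError("dmax must be at least 1")
    rng = np.random.default_rng(seed)
    anchors = np.sort(rng.choice(n, size=n_sample, replace=False))
    dist_to_all = cdist(A[anchors], A)
    # subcluster: the anchor's (dmax + 1) nearest neighbors (anchor included)
    nn = np.argsort(dist_to_all, axis=1, kind="stable")[:, : dmax + 1]
    if nn.shape[1] < 2:
        raise ValueError("subclusters need at least two points")
    bases = [_principal_subspace(A[nn[i]], dmax) for i in range(n_sample)]
    D = np.zeros((n_sample, n_sample))
    for i in range(n_sample):
        for j in range(i + 1, n_sample):
            D[i, j] = D[j, i] = _subspace_affinity(bases[i], bases[j])
    # sparsify: keep the dmax largest entries per row
    keep = min(dmax, n_sample - 1)
    S = np.zeros_like(D)
    for i in range(n_sample):
        top = np.argsort(D[i], kind="stable")[::-1][:keep]
        S[i, top] = D[i, top]
    S = S + S.T
    S = S / max(S.max(), 1e-30)
    np.fill_diagonal(S, 0.0)
    wm = WeightMatrix(S, sigma=1.0, metric_name="subspace-affinity")
    l_in = _spectral_cluster_from_weights(wm, k, seed).labels
    # out-of-sample: label of the nearest sampled anchor
    labels = np.empty(n, dtype=int)
    nearest_anchor = np.argmin(dist_to_all, axis=0)
    labels[:] = l_in[nearest_anchor]
    labels[anchors] = l_in
    return labels


def select_representatives(
    X, assignment: ClusterAssignment, target_n: int, seed: int = 0
) -> tuple[EpochMatrix, np.ndarray]:
    """Keep ``target_n`` rows: per-cluster quotas by largest-remainder rounding,
    filling each quota with the rows closest to the cluster centroid."""
    ep = X if isinstance(X, EpochMatrix) else EpochMatrix(np.asarray(X, dtype=float))
    A = ep.X
    n = A.shape[0]
    if target_n > n:
        raise ValueError("target_n cannot exceed the number of rows")
    if target_n < assignment.K:
        raise ValueError("target_n must be at least the number of clusters")
    sizes = np.bincount(assignment.labels, minlength=assignment.K)
    exact = target_n * sizes / n
    quotas = np.floor(exact).astype(int)
    quotas = np.maximum(quotas, 1)  # every cluster keeps a representative
    remainder = exact - np.floor(exact)
    while quotas.sum() < target_n:
        order = np.argsort(-remainder, kind="stable")
        for k in order:
            if quotas.sum() >= target_n:
                break
            if quotas[k] < sizes[k]:
                quotas[k] += 1
                remainder[k] = -1
    while quotas.sum() > target_n:  # possible after the min-1 floor
        k = int(np.argmax(quotas - exact))
        quotas[k] -= 1
    chosen: list[int] = []
    for k in range(assignment.K):
        members = np.flatnonzero(assignment.labels == k)
        d = np.linalg.norm(A[members] - assignment.centroids[k], axis=1)
        order = members[np.argsort(d, kind="stable")]
        chosen.extend(order[: quotas[k]].tolist())
    idx = np.sort(np.asarray(chosen, dtype=int))
    return ep.take(idx), idx
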