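"""Ranking and synchronization from noisy pairwise comparisons via SVD.

Latent per-item scores ``r`` are observed only through antisymmetric pairwise
measurements ``R_ij ~ r_i - r_j`` (possibly corrupted) on the edges of a
measurement graph.  The skew-symmetric measurement matrix ``H`` is rank 2 in
the noise-free complete case with left singular vectors spanning
``{e, r - mean(r) e}``; projecting out the all-ones direction inside the top
singular subspace recovers the score direction, the global sign is fixed by
minimizing upsets, and the scale by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import EpochMatrix


@dataclass
class MeasurementGraph:
    """Undirected graph with one antisymmetric measurement per edge.

    ``R[(i, j)]`` with ``i < j`` stores the measurement oriented ``i -> j``
    (i.e. an estimate of ``r_i - r_j``).
    """

    n: int
    edges: list[tuple[int, int]]
    R: dict[tuple[int, int], float]
    M_bound: float = 1.0
    p: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        self.edges = [tuple(sorted(e)) for e in self.edges]
        if set(self.edges) != set(self.R):
            raise ValueError("measurements must be defined exactly on the edges")


@dataclass
class MeasurementMatrix:
    H: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if not np.allclose(H, -H.T, atol=1e-10):
            raise ValueError("measurement matrix must be skew-symmetric")
        self.H = H


@dataclass
class RankSyncResult:
    pi_hat: np.ndarray  # node indices ordered by descending score
    r_hat: np.ndarray  # centered score estimates
    sigma_top: tuple[float, float]
    upsets: int


def build_measurement_matrix(g: MeasurementGraph) -> MeasurementMatrix:
    """``H_ij = R_ij`` and ``H_ji = -R_ij`` on edges, zero elsewhere."""
    H = np.zeros((g.n, g.n))
    for (i, j), r in g.R.items():
        H[i, j] = r
        H[j, i] = -r
    return MeasurementMatrix(H)


def _count_upsets(r_hat: np.ndarray, g: MeasurementGraph) -> int:
    """Edges whose measured sign disagrees with the recovered score ordering
    (ties on either side are excluded)."""
    upsets = 0
    for (i, j), rij in g.R.items():
        s_meas = np.sign(rij)
        s_est = np.sign(r_hat[i] - r_hat[j])
        if s_meas != 0 and s_est != 0 and s_meas != s_est:
            upsets += 1
    return upsets


def svd_rank_sync(H: MeasurementMatrix, g: MeasurementGraph) -> RankSyncResult:
    """Recover centered scores and the induced ranking from ``H``.

    Steps: top-2 left singular vectors of H; project ``e/sqrt(n)`` onto their
    span; take the in-span unit vector orthogonal to that projection as the
    score direction; resolve the sign by upset minimization; recover the
    scale ``tau`` by least squares of the observed entries of H against
    ``tau (u e^T - e u^T)``; center.
    """
    A = H.H
    n = A.shape[0]
    U, s, _ = np.linalg.svd(A)
    if s.size < 2 or s[1] < 1e-12:
        raise ValueError("insufficient signal: measurement matrix is rank deficient")
    span = U[:, :2]
    e_unit = np.ones(n) / np.sqrt(n)
    coef = span.T @ e_unit
    u_bar = span @ coef  # projection of e/sqrt(n) onto the top singular span
    # in-span direction orthogonal to u_bar
    ortho_coef = np.array([-coef[1], coef[0]])
    if np.linalg.norm(ortho_coef) < 1e-12:
        raise ValueError("insufficient signal: ones direction spans the singular space")
    u2 = span @ (ortho_coef / np.linalg.norm(ortho_coef))

    # sign: minimize upsets
    up_pos = _count_upsets(u2, g)
    up_neg = _count_upsets(-u2, g)
    if up_neg < up_pos:
        u2, upsets = -u2, up_neg
    else:
        upsets = up_pos

    # scale: least squares of observed H entries against (u e^T - e u^T)
    num = den = 0.0
    for (i, j), rij in g.R.items():
        a = u2[i] - u2[j]
        num += a * rij
        den += a * a
    tau = num / den if den > 0 else 0.0
    if tau < 0:  # least-squares scale should agree with the upset-chosen sign
        tau = abs(tau)
    r_hat = tau * u2
    r_hat = r_hat - r_hat.mean()
    pi_hat = np.argsort(-r_hat, kind="stable")
    return RankSyncResult(pi_hat, r_hat, (float(s[0]), float(s[1])), upsets)


def reduce_by_ranking(X, scores: np.ndarray, factor: float) -> tuple[EpochMatrix, np.ndarray]:
    """Retain the ``ceil(n / factor)`` rows with the highest scores, in stable
    original order; returns the reduced matrix and the kept indices."""
    ep = X if isinstance(X, EpochMatrix) else EpochMatrix(np.asarray(X, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if len(scores) != ep.n_epochs:
        raise ValueError("scores length must match row count")
    if factor < 1:
        raise ValueError("factor must be at least 1")
    m = int(np.ceil(ep.n_epochs / factor))
    top = np.argsort(-scores, kind="stable")[:m]
    idx = np.sort(top)
    return ep.take(idx), idx


def epoch_measurement_graph(
    X, n_neighbors: int = 10, seed: int = 0
) -> tuple[MeasurementGraph, np.ndarray]:
    """Pairwise-comparison graph over epochs for the ranking reduction.

    The pairwise-comparison model needs per-edge score differences, which
    epochs do not come with; here each epoch's score is its projection on the
    leading principal component of the (centered) epoch matrix and
    ``R_ij = s_i - s_j`` on a symmetrized k-nearest-neighbor graph.
    """
    from sklearn.neighbors import NearestNeighbors

    A = X.X if isinstance(X, EpochMatrix) else np.asarray(X, dtype=float)
    n = A.shape[0]
    C = A - A.mean(axis=0)
    _, _, Vt = np.linalg.svd(C, full_matrices=False)
    s = C @ Vt[0]
    k = min(n_neighbors + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(A)
    _, idx = nn.kneighbors(A)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    edges = sorted(edges)
    R = {(i, j): float(s[i] - s[j]) for i, j in edges}
    g = MeasurementGraph(
        n=n, edges=list(edges), R=R, M_bound=float(np.abs(s).max()), p=len(edges) / max(n * (n - 1) / 2, 1), eta=1.0
    )
    return g, s
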