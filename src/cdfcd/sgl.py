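"""Sparse group lasso with dual-level (group + feature) safe screening.

Primal problem, for a grouped design with blocks ``X_g``::

    min_beta  0.5 ||y - sum_g X_g beta_g||^2
              + alpha * lam * sum_g sqrt(n_g) ||beta_g||_2
              + lam * ||beta||_1

The dual variable is ``theta = (y - X beta) / lam``; at the optimum it is
feasible, i.e. for every group ``||S_1(X_g' theta)||_2 <= alpha sqrt(n_g)``
where ``S_1`` is the entrywise soft-threshold at 1.  Screening evaluates
upper bounds of those dual correlations over a sphere known to contain the
optimal dual point (radius from the duality gap, center from a warm-started
solution), discarding groups and features that are provably zero at the
optimum before solving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq


@dataclass
class GroupedDesign:
    """Design matrix with a column partition into feature groups."""

    X: np.ndarray
    y: np.ndarray
    groups: list[np.ndarray]  # column indices per group

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        q = self.X.shape[1]
        flat = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        if sorted(flat.tolist()) != list(range(q)):
            raise ValueError("groups must partition all columns")
        if any(len(g) < 1 for g in self.groups):
            raise ValueError("every group needs at least one feature")

    @property
    def G(self) -> int:
        return len(self.groups)

    def block(self, g: int) -> np.ndarray:
        return self.X[:, self.groups[g]]


@dataclass
class SelectionResult:
    beta: np.ndarray
    active_groups: np.ndarray
    active_features: np.ndarray
    lam: float
    alpha: float
    screened_groups: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    screened_features: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _group_prox(v: np.ndarray, t_l1: float, t_group: float) -> np.ndarray:
    """Prox of ``t_group ||.||_2 + t_l1 ||.||_1`` (soft-threshold then group shrink)."""
    u = _soft(v, t_l1)
    nrm = np.linalg.norm(u)
    if nrm <= t_group:
        return np.zeros_like(u)
    return u * (1.0 - t_group / nrm)


def sgl_objective(d: GroupedDesign, beta: np.ndarray, lam: float, alpha: float) -> float:
    r = d.y - d.X @ beta
    pen = sum(
        np.sqrt(len(g)) * np.linalg.norm(beta[g]) for g in d.groups
    )
    return float(0.5 * r @ r + alpha * lam * pen + lam * np.abs(beta).sum())


def sgl_dual_objective(d: GroupedDesign, theta: np.ndarray, lam: float) -> float:
    return float(0.5 * d.y @ d.y - 0.5 * lam**2 * np.sum((d.y / lam - theta) ** 2))


def _dual_feasible_point(d: GroupedDesign, r: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    """Rescale the residual-based dual candidate ``r / lam`` into the feasible set."""
    theta = r / lam
    scale = 1.0
    for g in d.groups:
        corr = d.X[:, g].T @ theta
        nrm = np.linalg.norm(_soft(corr, 1.0))
        bound = alpha * np.sqrt(len(g))
        if nrm > bound:
            cmax = np.abs(corr).max()
            if bound <= 0:  # pure-l1 group: need |corr| <= 1 entrywise
                scale = min(scale, 1.0 / cmax)
                continue
            # feasibility along the ray t*theta: ||S_1(t c)|| increases in t
            f = lambda t: np.linalg.norm(_soft(corr * t, 1.0)) - bound
            lo = 0.999 / cmax  # below here S_1 vanishes, f = -bound < 0
            if f(1.0) > 0:
                scale = min(scale, brentq(f, lo, 1.0, xtol=1e-12))
    return theta * scale


def duality_gap(d: GroupedDesign, beta: np.ndarray, lam: float, alpha: float) -> float:
    r = d.y - d.X @ beta
    theta = _dual_feasible_point(d, r, lam, alpha)
    return sgl_objective(d, beta, lam, alpha) - sgl_dual_objective(d, theta, lam)


def lambda_max(d: GroupedDesign, alpha: float) -> float:
    """Smallest lam at which beta = 0 is optimal.

    beta = 0 is optimal iff theta = y / lam is dual feasible; per group the
    critical lam solves ``||S_1(X_g' y / lam)||_2 = alpha sqrt(n_g)``.
    """
    lam = 0.0
    for g in d.groups:
        c = d.X[:, g].T @ d.y
        bound = alpha * np.sqrt(len(g))
        hi = np.abs(c).max()
        if hi <= 0:
            continue
        f = lambda l: np.linalg.norm(_soft(c / l, 1.0)) - bound
        if f(hi) >= 0:  # still infeasible at lam where all |c|/lam = 1
            lam = max(lam, hi)
            continue
        lo = hi * 1e-10
        if f(lo) <= 0:
            continue
        lam = max(lam, brentq(f, lo, hi, xtol=1e-12))
    return lam if lam > 0 else 1e-12


def sgl_solve(
    d: GroupedDesign,
    lam: float,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 2000,
    beta0: np.ndarray | None = None,
    active_set: np.ndarray | None = None,
) -> np.ndarray:
    """Block coordinate (proximal) descent minimizer of the SGL objective.

    ``active_set`` restricts updates to the given group indices (used by
    screening); excluded groups stay at their ``beta0`` value (zero).
    Convergence is declared at duality gap below ``tol`` (scaled by the
    null objective).
    """
    if lam < 0 or alpha < 0:
        raise ValueError("lam and alpha must be nonnegative")
    q = d.X.shape[1]
    beta = np.zeros(q) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    groups = range(d.G) if active_set is None else [int(g) for g in active_set]
    lips = {}
    for g in groups:
        Xg = d.block(g)
        lips[g] = max(np.linalg.norm(Xg, 2) ** 2, 1e-12)
    r = d.y - d.X @ beta
    scale = max(0.5 * d.y @ d.y, 1e-12)
    for it in range(max_iter):
        max_move = 0.0
        for g in groups:
            idx = d.groups[g]
            Xg = d.X[:, idx]
            bg = beta[idx]
            grad = -Xg.T @ r
            if lam > 0:
                # group-level zero check at the current residual
                v = bg - grad / lips[g]
                new = _group_prox(
                    v, lam / lips[g], alpha * lam * np.sqrt(len(idx)) / lips[g]
                )
            else:
                new = bg - grad / lips[g]
            delta = new - bg
            if np.any(delta):
                r = r - Xg @ delta
                beta[idx] = new
                max_move = max(max_move, np.abs(delta).max())
        if lam > 0:
            if it % 5 == 4 or max_move == 0.0:
                gap = duality_gap(d, beta, lam, alpha)
                if gap <= tol * scale:
                    return beta
        elif max_move <= 1e-12:
            return beta
    if lam > 0:
        gap = duality_gap(d, beta, lam, alpha)
        if gap > tol * scale:
            warnings.warn(f"SGL did not reach tolerance: final gap {gap:.3e}")
    return beta


def sgl_dual_screen(
    d: GroupedDesign,
    lam: float,
    alpha: float,
    theta_center: np.ndarray,
    radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sphere-test safe screening.

    Over the ball ``Theta = B(theta_center, radius)`` containing the optimal
    dual point, upper-bound the group statistic
    ``s_g* = sup ||S_1(X_g' theta)||`` by the Lipschitz bound
    ``||S_1(X_g' theta_c)|| + ||X_g||_2 * radius`` and the feature statistic
    ``t_gk* = sup |x_gk' theta|`` by ``|x_gk' theta_c| + ||x_gk|| * radius``.
    Groups with ``s_g* < alpha sqrt(n_g)`` and features with ``t_gk* <= 1``
    are provably zero at the optimum.
    """
    if radius < 0:
        raise ValueError("screening region radius must be nonnegative")
    screened_groups, screened_features = [], []
    for g, idx in enumerate(d.groups):
        Xg = d.X[:, idx]
        corr = Xg.T @ theta_center
        s_star = np.linalg.norm(_soft(corr, 1.0)) + np.linalg.norm(Xg, 2) * radius
        if s_star < alpha * np.sqrt(len(idx)):
            screened_groups.append(g)
            screened_features.extend(idx.tolist())
            continue
        col_norms = np.linalg.norm(Xg, axis=0)
        t_star = np.abs(corr) + col_norms * radius
        screened_features.extend(idx[t_star <= 1.0].tolist())
    return np.asarray(screened_groups, dtype=int), np.asarray(sorted(screened_features), dtype=int)


def sgl_dli_select(
    d: GroupedDesign,
    lambda_path: np.ndarray | None = None,
    alpha: float = 0.5,
    budget: int | None = None,
    tol: float = 1e-8,
    use_screening: bool = True,
) -> SelectionResult:
    """Pathwise SGL with dual-level screening; returns the path solution whose
    active-feature count is closest to ``budget`` without exceeding it.

    Default path: 30 log-spaced values from ``lambda_max`` down to 1% of it.
    """
    q = d.X.shape[1]
    budget = q if budget is None else int(budget)
    if budget > q:
        raise ValueError("budget cannot exceed the number of features")
    if lambda_path is None:
        lmax = lambda_max(d, alpha)
        lambda_path = np.geomspace(lmax, 0.01 * lmax, 30)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if lambda_path.size == 0:
        raise ValueError("empty regularization path")
    best: SelectionResult | None = None
    beta = np.zeros(q)
    prev_lam = None
    for lam in lambda_path:
        if use_screening and prev_lam is not None:
            # sphere from the warm-start solution evaluated at the new lam
            r = d.y - d.X @ beta
            theta_c = _dual_feasible_point(d, r, lam, alpha)
            gap = sgl_objective(d, beta, lam, alpha) - sgl_dual_objective(d, theta_c, lam)
            radius = np.sqrt(max(2.0 * gap, 0.0)) / lam
            sg, sf = sgl_dual_screen(d, lam, alpha, theta_c, radius)
            active = np.setdiff1d(np.arange(d.G), sg)
        else:
            sg = np.array([], dtype=int)
            sf = np.array([], dtype=int)
            active = np.arange(d.G)
        beta = sgl_solve(d, lam, alpha, tol=tol, beta0=beta, active_set=active)
        nz = np.flatnonzero(np.abs(beta) > 1e-12)
        ag = np.array(
            [g for g, idx in enumerate(d.groups) if np.abs(beta[idx]).max() > 1e-12],
            dtype=int,
        )
        if len(nz) <= budget and (best is None or len(nz) > len(best.active_features)):
            best = SelectionResult(beta.copy(), ag, nz, float(lam), alpha, sg, sf)
        prev_lam = lam
    if best is None:  # even the sparsest solution exceeds the budget
        best = SelectionResult(beta.copy(), ag, nz, float(lambda_path[-1]), alpha, sg, sf)
    return best
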