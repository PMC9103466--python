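"""Variational Bayesian matrix factorization with a fully factorized posterior.

Model: ``Z ~ U^T V + noise`` with ``U`` (K x P) and ``V`` (K x Q), Gaussian
observation noise of variance ``sigma2`` on the observed entries ``Omega``,
and zero-mean Gaussian priors on the factor entries with per-component
(ARD) prior variances.  The variational posterior factorizes over every
scalar entry of U and V, giving closed-form coordinate-ascent updates; the
noise variance and ARD prior variances are updated in closed form as well,
so the evidence lower bound is non-decreasing across sweeps.  Components
unsupported by the data shrink toward zero (automatic rank pruning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class VBMFResult:
    U: np.ndarray  # posterior means, K x P
    V: np.ndarray  # posterior means, K x Q
    noise_var: float
    elbo_trace: np.ndarray
    U_var: np.ndarray = None
    V_var: np.ndarray = None

    def reconstruction(self) -> np.ndarray:
        return self.U.T @ self.V


def _elbo(Z, mask, mu, mv, su, sv, sigma2, cu, cv) -> float:
    n_obs = mask.sum()
    Eu2 = mu**2 + su
    Ev2 = mv**2 + sv
    pred = mu.T @ mv
    # E[(z - u'v)^2] = (z - m_u'm_v)^2 + sum_k (m_uk^2 s_vk + s_uk m_vk^2 + s_uk s_vk)
    var_term = (mu**2).T @ sv + su.T @ (mv**2) + su.T @ sv
    err2 = (Z - pred) ** 2 + var_term
    like = -0.5 * n_obs * np.log(2 * np.pi * sigma2) - 0.5 * (mask * err2).sum() / sigma2
    # KL(q||p) for independent Gaussians, per factor row k with prior var c_k
    klu = 0.5 * np.sum((Eu2 / cu[:, None]) - 1.0 + np.log(cu[:, None] / su))
    klv = 0.5 * np.sum((Ev2 / cv[:, None]) - 1.0 + np.log(cv[:, None] / sv))
    return float(like - klu - klv)


def vbmf(
    Z: np.ndarray,
    K: int,
    mask: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    seed: int = 0,
    update_priors: bool = True,
) -> VBMFResult:
    """Fit a rank-K variational Bayesian factorization of ``Z``.

    ``mask`` marks observed entries (default: all observed).  Deterministic
    given ``seed`` (used only for the factor initialization).
    """
    Z = np.asarray(Z, dtype=float)
    P, Q = Z.shape
    if K < 1 or K > min(P, Q):
        raise ValueError("K must satisfy 1 <= K <= min(P, Q)")
    mask = np.ones_like(Z, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no observed entries")
    rng = np.random.default_rng(seed)
    # truncated-SVD initialization (zero-filled missing entries) avoids the
    # null fixed point of the coordinate ascent; jitter breaks symmetry
    Z0 = np.where(mask, Z, 0.0)
    U0, s0, V0t = np.linalg.svd(Z0, full_matrices=False)
    root = np.sqrt(s0[:K])
    mu = (U0[:, :K] * root).T + 1e-3 * rng.standard_normal((K, P))
    mv = (root[:, None] * V0t[:K]) + 1e-3 * rng.standard_normal((K, Q))
    su = np.ones((K, P))
    sv = np.ones((K, Q))
    cu = np.ones(K)
    cv = np.ones(K)
    sigma2 = max(float(np.var(Z[mask])), 1e-12) or 1.0
    Zm = np.where(mask, Z, 0.0)
    elbo_trace = []
    for it in range(max_iter):
        # update U columns (each p independently across k sequentially)
        for k in range(K):
            Ev2 = mv[k] ** 2 + sv[k]
            prec = 1.0 / cu[k] + (mask @ Ev2) / sigma2
            resid = Zm - np.where(mask, mu.T @ mv, 0.0) + np.outer(mu[k], mv[k]) * mask
            lin = (resid * mv[k][None, :]).sum(axis=1) / sigma2
            su[k] = 1.0 / prec
            mu[k] = lin / prec
        for k in range(K):
            Eu2 = mu[k] ** 2 + su[k]
            prec = 1.0 / cv[k] + (mask.T @ Eu2) / sigma2
            resid = Zm - np.where(mask, mu.T @ mv, 0.0) + np.outer(mu[k], mv[k]) * mask
            lin = (resid * mu[k][:, None]).sum(axis=0) / sigma2
            sv[k] = 1.0 / prec
            mv[k] = lin / prec
        if update_priors:
            cu = np.maximum((mu**2 + su).mean(axis=1), 1e-12)
            cv = np.maximum((mv**2 + sv).mean(axis=1), 1e-12)
        pred = mu.T @ mv
        var_term = (mu**2).T @ sv + su.T @ (mv**2) + su.T @ sv
        err2 = (Z - pred) ** 2 + var_term
        sigma2 = max(float((mask * err2).sum() / mask.sum()), 1e-12)
        elbo_trace.append(_elbo(Z, mask, mu, mv, su, sv, sigma2, cu, cv))
        if it > 0 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol * (1 + abs(elbo_trace[-2])):
            break
    pruned = (np.abs(mu).max(axis=1) * np.abs(mv).max(axis=1)) < 1e-8
    if pruned.any():
        warnings.warn(f"{pruned.sum()} factor component(s) pruned to near zero")
    return VBMFResult(mu, mv, sigma2, np.asarray(elbo_trace), su, sv)
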