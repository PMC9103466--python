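"""Multiclass Gaussian process classification with a label-noise likelihood.

One latent function per class with a squared-exponential GP prior; the label
is the argmax of the latents.  Annotation errors are modelled by corrupting
the argmax rule with probability ``eps``: the likelihood of an observed
label is ``1 - eps`` when its latent wins strictly and ``eps / (C - 1)``
otherwise.  Inference is variational: a factorized Gaussian posterior over
the per-class latent vectors is fit by stochastic gradient ascent (Adam) on
the evidence lower bound, with the likelihood expectation estimated by
Monte Carlo over the posterior (Rao-Blackwellized across the non-target
classes, which enter through Gaussian CDFs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm


def kernel_se(x: np.ndarray, x_prime: np.ndarray, theta: dict) -> float:
    """Squared-exponential covariance with per-dimension length scales.

    ``sigma2 * exp(-0.5 * sum_j (x_j - x'_j)^2 / l_j) + 1[x == x'] * sigma02``.
    """
    x = np.asarray(x, dtype=float)
    xp = np.asarray(x_prime, dtype=float)
    l = np.asarray(theta["l"], dtype=float)
    if np.any(l <= 0) or theta["sigma2"] <= 0:
        raise ValueError("kernel hyperparameters must be positive")
    val = theta["sigma2"] * np.exp(-0.5 * np.sum((x - xp) ** 2 / l))
    if np.array_equal(x, xp):
        val += theta.get("sigma02", 0.0)
    return float(val)


def _kernel_matrix(A: np.ndarray, B: np.ndarray | None, theta: dict) -> np.ndarray:
    l = np.asarray(theta["l"], dtype=float)
    As = A / np.sqrt(l)
    Bs = As if B is None else B / np.sqrt(l)
    D2 = cdist(As, Bs, metric="sqeuclidean")
    K = theta["sigma2"] * np.exp(-0.5 * D2)
    if B is None:
        K = K + theta.get("sigma02", 0.0) * np.eye(A.shape[0])
    return K


def likelihood_eps(y_i: int, f_i: np.ndarray, eps: float) -> float:
    """Eq.-of-motion of the corrupted argmax rule (strict inequalities).

    Returns ``(1-eps) * prod_{c != y} step(f_y - f_c)`` plus the corruption
    branch ``eps/(C-1)`` when the target latent does not win strictly.
    """
    f_i = np.asarray(f_i, dtype=float)
    C = len(f_i)
    if C < 2:
        raise ValueError("need at least two classes")
    if not (0 <= eps < 1):
        raise ValueError("eps must lie in [0, 1)")
    others = np.delete(f_i, y_i - 1)
    wins = float(np.all(f_i[y_i - 1] > others))  # step(0) = 0
    return (1.0 - eps) * wins + eps / (C - 1) * (1.0 - wins)


@dataclass
class MGCModel:
    C: int
    kernel_params: list[dict]
    m: np.ndarray  # variational means, C x n
    s: np.ndarray  # variational variances, C x n
    eps: float
    X_train: np.ndarray
    elbo_trace: np.ndarray
    seed: int = 0


def _elbo_lik_grads(m, s, y, eps, zeta):
    """Likelihood part of the ELBO and its gradients wrt (m, s).

    ``E[log p(y_i | f_i)] = Q_i log(1-eps) + (1-Q_i) log(eps/(C-1))`` where
    ``Q_i`` is the posterior probability that the target latent wins; the
    target latent is sampled (reparameterized, draws ``zeta``), the other
    classes are marginalized through Gaussian CDFs.
    """
    C, n = m.shape
    idx = np.arange(n)
    sd = np.sqrt(s)
    m_y, sd_y = m[y, idx], sd[y, idx]
    t = m_y[None, :] + sd_y[None, :] * zeta[:, None]  # S x n
    a = (t[None, :, :] - m[:, None, :]) / sd[:, None, :]  # C x S x n
    P = norm.cdf(a)
    phi = norm.pdf(a)
    is_y = np.zeros((C, n), dtype=bool)
    is_y[y, idx] = True
    P = np.where(is_y[:, None, :], 1.0, P)
    phi = np.where(is_y[:, None, :], 0.0, phi)
    prod = P.prod(axis=0)  # S x n
    Q = prod.mean(axis=0)
    # leave-one-out products g_c = phi_c * prod_{c' != c} P_c' / sd_c
    Psafe = np.maximum(P, 1e-300)
    loo = prod[None, :, :] / Psafe
    g = phi * loo / sd[:, None, :]  # C x S x n
    gsum = g.sum(axis=0)  # S x n
    S = len(zeta)
    dQ_dm = -g.mean(axis=1)  # from m_c of non-target classes
    dQ_dm[y, idx] += gsum.mean(axis=0)
    dQ_dsd = -(g * a).mean(axis=1)
    dQ_dsd[y, idx] += (gsum * zeta[:, None]).mean(axis=0)
    w = np.log((1.0 - eps) * (C - 1) / eps) if eps > 0 else None
    if w is None:
        raise ValueError("eps must be positive for a finite evidence bound")
    lik = Q * np.log(1 - eps) + (1 - Q) * np.log(eps / (C - 1))
    dlik_dm = w * dQ_dm
    dlik_ds = w * dQ_dsd / (2.0 * sd)
    return float(lik.sum()), dlik_dm, dlik_ds, Q


def _kl_and_grads(m, s, Kinvs, logdets):
    C, n = m.shape
    kl = 0.0
    dm = np.zeros_like(m)
    ds = np.zeros_like(s)
    for c in range(C):
        Kinv = Kinvs[c]
        Km = Kinv @ m[c]
        diagKinv = np.diag(Kinv)
        kl += 0.5 * (
            np.sum(diagKinv * s[c]) + m[c] @ Km - n + logdets[c] - np.sum(np.log(s[c]))
        )
        dm[c] = Km
        ds[c] = 0.5 * (diagKinv - 1.0 / s[c])
    return float(kl), dm, ds


def mgc_fit(
    X: np.ndarray,
    y: np.ndarray,
    C: int | None = None,
    eps: float = 0.05,
    seed: int = 0,
    max_iter: int = 300,
    n_mc: int = 64,
    lr: float = 0.05,
    patience: int = 60,
) -> MGCModel:
    """Fit the variational multiclass GP classifier.

    Labels are 1-based in {1..C} (0-based arrays are accepted and shifted).
    Kernel length scales start from the per-dimension median heuristic; the
    amplitude and a shared length-scale factor are refined by coordinate
    search on the bound during training.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.min() == 0:
        y = y + 1
    C = int(y.max()) if C is None else int(C)
    n, d = X.shape
    if n < C:
        raise ValueError("need at least as many points as classes")
    y0 = y - 1
    eps_fit = max(eps, 1e-6)  # keep the bound finite when eps = 0
    rng = np.random.default_rng(seed)
    zeta = rng.standard_normal(n_mc)

    var_j = np.maximum(X.var(axis=0), 1e-12)
    base_l = d * var_j  # median-heuristic-style scaling of Eq-21 length scales
    theta = {"sigma2": 1.0, "sigma02": 1e-3, "l": base_l.copy()}
    kernel_params = [dict(theta) for _ in range(C)]

    def priors(params):
        Kinvs, logdets = [], []
        for th in params:
            K = _kernel_matrix(X, None, th) + 1e-8 * np.eye(n)
            L = np.linalg.cholesky(K)
            Kinv = np.linalg.inv(L).T @ np.linalg.inv(L)
            Kinvs.append(Kinv)
            logdets.append(2.0 * np.sum(np.log(np.diag(L))))
        return Kinvs, logdets

    Kinvs, logdets = priors(kernel_params)

    m = np.zeros((C, n))
    m[y0, np.arange(n)] = 1.0  # mild supervised initialization
    rho = np.zeros((C, n))  # s = exp(rho)

    adam_m = {k: 0.0 for k in ("m", "rho")}
    adam_v = {k: 0.0 for k in ("m", "rho")}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    trace = []
    best_elbo, since_best = -np.inf, 0
    for it in range(1, max_iter + 1):
        s = np.exp(rho)
        lik, dlm, dls, _ = _elbo_lik_grads(m, s, y0, eps_fit, zeta)
        kl, dkm, dks, = _kl_and_grads(m, s, Kinvs, logdets)
        elbo = lik - kl
        trace.append(elbo)
        gm = dlm - dkm
        grho = (dls - dks) * s
        for key, g in (("m", gm), ("rho", grho)):
            adam_m[key] = b1 * adam_m[key] + (1 - b1) * g
            adam_v[key] = b2 * adam_v[key] + (1 - b2) * g**2
            mh = adam_m[key] / (1 - b1**it)
            vh = adam_v[key] / (1 - b2**it)
            step = lr * mh / (np.sqrt(vh) + eps_adam)
            if key == "m":
                m = m + step
            else:
                rho = np.clip(rho + step, -10.0, 5.0)
        if elbo > best_elbo + 1e-6:
            best_elbo, since_best = elbo, 0
        else:
            since_best += 1
            if since_best >= patience:
                warnings.warn(f"MGC early stop at iteration {it}: no bound improvement")
                break
        # coordinate refinement of shared kernel scale/amplitude on the bound
        if it % 50 == 0:
            s = np.exp(rho)
            best_fac, best_kl = (1.0, 1.0), None
            for lf in (0.5, 1.0, 2.0):
                for af in (0.5, 1.0, 2.0):
                    cand = [
                        {"sigma2": th["sigma2"] * af, "sigma02": th["sigma02"], "l": th["l"] * lf}
                        for th in kernel_params
                    ]
                    ki, ld = priors(cand)
                    klc, _, _ = _kl_and_grads(m, s, ki, ld)
                    if best_kl is None or klc < best_kl:
                        best_kl, best_fac, best_pr = klc, (lf, af), (ki, ld)
            lf, af = best_fac
            if (lf, af) != (1.0, 1.0):
                kernel_params = [
                    {"sigma2": th["sigma2"] * af, "sigma02": th["sigma02"], "l": th["l"] * lf}
                    for th in kernel_params
                ]
                Kinvs, logdets = best_pr
    return MGCModel(
        C=C,
        kernel_params=kernel_params,
        m=m,
        s=np.exp(rho),
        eps=eps,
        X_train=X,
        elbo_trace=np.asarray(trace),
        seed=seed,
    )


def mgc_predict(
    model: MGCModel, X_star: np.ndarray, n_mc: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-predictive labels and class probabilities (Monte Carlo)."""
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if X_star.shape[1] != model.X_train.shape[1]:
        raise ValueError("feature dimension mismatch with training data")
    n_star = X_star.shape[0]
    rng = np.random.default_rng(model.seed + 1)
    mu = np.zeros((model.C, n_star))
    var = np.zeros((model.C, n_star))
    for c in range(model.C):
        th = model.kernel_params[c]
        K = _kernel_matrix(model.X_train, None, th) + 1e-8 * np.eye(len(model.X_train))
        Ks = _kernel_matrix(model.X_train, X_star, th)
        sol = np.linalg.solve(K, Ks)
        mu[c] = sol.T @ model.m[c]
        kss = th["sigma2"] + th.get("sigma02", 0.0)
        var[c] = np.maximum(
            kss - np.sum(Ks * sol, axis=0) + np.sum(sol**2 * model.s[c][:, None], axis=0),
            1e-12,
        )
    draws = mu[:, None, :] + np.sqrt(var)[:, None, :] * rng.standard_normal(
        (model.C, n_mc, n_star)
    )
    winners = np.argmax(draws, axis=0)  # n_mc x n_star
    P_win = np.stack([(winners == c).mean(axis=0) for c in range(model.C)])
    probs = (1 - model.eps) * P_win + model.eps / (model.C - 1) * (1 - P_win)
    probs = probs / probs.sum(axis=0, keepdims=True)
    labels = np.argmax(probs, axis=0) + 1
    return labels, probs.T
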