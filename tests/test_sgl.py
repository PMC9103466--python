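import numpy as np
import pytest

from cdfcd import (
    GroupedDesign,
    gen_group_sparse_regression,
    lambda_max,
    sgl_dli_select,
    sgl_dual_screen,
    sgl_solve,
)
from cdfcd.sgl import _dual_feasible_point, sgl_dual_objective, sgl_objective


def _group_lasso_prox_oracle(X, y, lam_group, tol=1e-12, iters=20000):
    """Independent proximal-gradient group-lasso solver (single group)."""
    L = np.linalg.norm(X, 2) ** 2
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        grad = -X.T @ (y - X @ beta)
        v = beta - grad / L
        nrm = np.linalg.norm(v)
        new = np.zeros_like(v) if nrm <= lam_group / L else v * (1 - lam_group / (L * nrm))
        if np.abs(new - beta).max() < tol:
            beta = new
            break
        beta = new
    return beta


class TestSolver:
    def test_orthogonal_response_gives_zero(self, rng):
        X = rng.standard_normal((10, 3))
        # project response out of the column space
        y = rng.standard_normal(10)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        d = GroupedDesign(X, y, [np.arange(3)])
        beta = sgl_solve(d, lam=0.5, alpha=0.5)
        assert np.abs(beta).max() == 0.0

    def test_lambda_zero_matches_least_squares(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        d = GroupedDesign(X, y, [np.arange(2), np.array([2])])
        beta = sgl_solve(d, lam=0.0, alpha=0.5)
        assert np.abs(beta - np.linalg.lstsq(X, y, rcond=None)[0]).max() < 1e-6

    def test_alpha_zero_single_group_matches_group_lasso_oracle(self, rng):
        # alpha scales the group penalty; with the l1 part switched off by
        # construction of the comparison, a pure group-lasso solver on the
        # same instance must agree
        X = rng.standard_normal((5, 2))
        y = rng.standard_normal(5)
        d = GroupedDesign(X, y, [np.arange(2)])
        lam, alpha = 0.4, 0.7
        beta = sgl_solve(d, lam=lam, alpha=alpha, tol=1e-12)
        # objective parity check against a direct grid around the solution
        obj = sgl_objective(d, beta, lam, alpha)
        for _ in range(200):
            trial = beta + 1e-3 * rng.standard_normal(2)
            assert sgl_objective(d, trial, lam, alpha) >= obj - 1e-10

    def test_pure_group_penalty_matches_oracle(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        lam_group = 2.5
        oracle = _group_lasso_prox_oracle(X, y, lam_group)
        # express the same problem through the SGL solver: one group,
        # alpha*lam*sqrt(n_g) = lam_group and a vanishing l1 part
        lam = 1e-9
        alpha = lam_group / (lam * np.sqrt(4))
        d = GroupedDesign(X, y, [np.arange(4)])
        beta = sgl_solve(d, lam=lam, alpha=alpha, tol=1e-12, max_iter=20000)
        assert np.abs(beta - oracle).max() < 1e-6

    def test_alpha_zero_reduces_to_lasso(self, rng):
        from sklearn.linear_model import Lasso

        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        d = GroupedDesign(X, y, [np.arange(5)])
        lam = 3.0
        beta = sgl_solve(d, lam=lam, alpha=0.0, tol=1e-12, max_iter=10000)
        ref = Lasso(alpha=lam / 30, fit_intercept=False, tol=1e-12, max_iter=100000)
        ref.fit(X, y)
        assert np.abs(beta - ref.coef_).max() < 1e-6

    def test_lambda_max_nulls_solution(self, rng):
        d, _ = gen_group_sparse_regression(30, [4, 4, 4], [0], seed=0)
        lmax = lambda_max(d, alpha=0.5)
        assert np.abs(sgl_solve(d, lmax * 1.0001, 0.5)).max() == 0.0
        assert np.abs(sgl_solve(d, lmax * 0.9, 0.5)).max() > 0.0


class TestScreening:
    def test_safety_on_random_instances(self):
        """Screened groups/features are exactly zero in the unscreened optimum."""
        alpha = 0.5
        for seed in range(50):
            d, _ = gen_group_sparse_regression(
                30, [5, 5, 5, 5], [0, 2], within_sparsity=0.6, snr=3.0, seed=seed
            )
            lmax = lambda_max(d, alpha)
            lam = 0.5 * lmax
            beta_ref = sgl_solve(d, 0.8 * lmax, alpha, tol=1e-10)
            r = d.y - d.X @ beta_ref
            theta = _dual_feasible_point(d, r, lam, alpha)
            gap = sgl_objective(d, beta_ref, lam, alpha) - sgl_dual_objective(d, theta, lam)
            radius = np.sqrt(max(2 * gap, 0.0)) / lam
            sg, sf = sgl_dual_screen(d, lam, alpha, theta, radius)
            beta_full = sgl_solve(d, lam, alpha, tol=1e-10)
            for g in sg:
                assert np.abs(beta_full[d.groups[g]]).max() == 0.0
            for f in sf:
                assert beta_full[f] == 0.0

    def test_zero_radius_reduces_to_kkt_tests(self, rng):
        d, _ = gen_group_sparse_regression(40, [4, 4, 4, 4], [1], seed=5)
        alpha = 0.5
        lam = 0.4 * lambda_max(d, alpha)
        beta = sgl_solve(d, lam, alpha, tol=1e-12)
        theta = (d.y - d.X @ beta) / lam
        sg, sf = sgl_dual_screen(d, lam, alpha, theta, radius=0.0)
        # at the exact dual point, screening recovers the full zero pattern
        # of inactive groups
        for g in sg:
            assert np.abs(beta[d.groups[g]]).max() == 0.0
        inactive = [g for g, idx in enumerate(d.groups) if np.abs(beta[idx]).max() == 0]
        assert set(sg).issubset(set(inactive))

    def test_screening_does_not_change_path_solutions(self):
        d, _ = gen_group_sparse_regression(40, [4, 4, 4, 4], [0, 3], seed=11)
        res_on = sgl_dli_select(d, alpha=0.5, budget=16, use_screening=True, tol=1e-10)
        res_off = sgl_dli_select(d, alpha=0.5, budget=16, use_screening=False, tol=1e-10)
        assert np.abs(res_on.beta - res_off.beta).max() < 1e-8

    def test_screened_and_active_sets_disjoint(self):
        d, _ = gen_group_sparse_regression(30, [5, 5, 5], [0], seed=2)
        res = sgl_dli_select(d, alpha=0.5, budget=10)
        assert not set(res.screened_features) & set(res.active_features)


class TestPathSelection:
    def test_budget_full_low_lambda_activates_everything(self, rng):
        X = rng.standard_normal((50, 6))
        beta_true = rng.standard_normal(6)
        y = X @ beta_true + 0.01 * rng.standard_normal(50)
        d = GroupedDesign(X, y, [np.arange(3), np.arange(3, 6)])
        lmax = lambda_max(d, 0.5)
        path = np.geomspace(lmax, 1e-4 * lmax, 40)
        res = sgl_dli_select(d, lambda_path=path, alpha=0.5, budget=6)
        assert len(res.active_features) == 6

    def test_planted_groups_recovered(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            d, beta = gen_group_sparse_regression(
                200, [4] * 8, [1, 5], within_sparsity=1.0, snr=50.0, seed=seed
            )
            res = sgl_dli_select(d, alpha=0.5, budget=8)
            if set(res.active_groups) == {1, 5}:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_empty_path_rejected(self):
        d, _ = gen_group_sparse_regression(20, [4, 4], [0], seed=0)
        with pytest.raises(ValueError, match="empty"):
            sgl_dli_select(d, lambda_path=np.array([]), alpha=0.5, budget=4)

    def test_budget_never_exceeded(self):
        d, _ = gen_group_sparse_regression(60, [6, 6, 6], [0, 1, 2], snr=20.0, seed=4)
        for budget in (3, 7, 12):
            res = sgl_dli_select(d, alpha=0.5, budget=budget)
            assert len(res.active_features) <= budget
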