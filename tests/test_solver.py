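"""PGD solver: backtracking, stopping, KKT certificate and the warm path."""

import numpy as np
import pytest

from sgpath import (
    CoefficientState,
    Hyperparameters,
    ProblemData,
    backtracking_step,
    compute_group_weights,
    compute_lambda_max,
    evaluate_objective,
    fit_path,
    kkt_residual,
    solve_single,
    unpenalized_baseline,
    validate_problem,
)

from _oracles import solve_oracle
from conftest import make_random_problem


def tight_hp(alpha, **kw):
    kw.setdefault("eps_rel", 1e-10)
    kw.setdefault("max_iter", 100000)
    return Hyperparameters(alpha=alpha, **kw)


class TestBacktrackingStep:
    def test_lipschitz_step_accepted_without_shrinking(self, rng):
        pr, gw = make_random_problem(rng, with_x=False)
        t0 = pr.n / np.linalg.norm(pr.Z.T @ pr.Z, 2)
        st = CoefficientState(np.zeros(0), rng.normal(size=pr.p))
        _, t = backtracking_step(pr, gw, st, 0.0, 0.5, t0, 0.5)
        assert t == t0

    def test_huge_step_is_shrunk_and_still_descends(self, rng):
        pr, gw = make_random_problem(rng, n=6, p=4, L=2)
        st = CoefficientState(rng.normal(size=pr.q), rng.normal(size=pr.p))
        lam, alpha = 0.2, 0.5
        f0 = evaluate_objective(pr, gw, st, lam, alpha)
        new, t = backtracking_step(pr, gw, st, lam, alpha, 1e6, 0.5)
        assert t < 1e6
        assert evaluate_objective(pr, gw, new, lam, alpha) <= f0 + 1e-12

    def test_zero_solution_is_fixed_point_at_lambda_max(self, rng):
        pr, gw = make_random_problem(rng)
        b0, r0 = unpenalized_baseline(pr)
        lam_max = compute_lambda_max(pr, gw, 0.5, r0=r0)
        st = CoefficientState(b0, np.zeros(pr.p))
        new, _ = backtracking_step(pr, gw, st, lam_max, 0.5, 1.0, 0.5)
        np.testing.assert_array_equal(new.u, 0.0)
        np.testing.assert_allclose(new.b, b0, atol=1e-12)
        assert kkt_residual(pr, gw, st, lam_max, 0.5) <= 1e-10


class TestSolveSingle:
    def test_identity_design_soft_threshold_solution(self):
        # stationarity for Z = I, n = 2, alpha = 1: u_j = ST(y_j, n*lam)
        pr = validate_problem(ProblemData(
            y=np.array([3.0, -1.0]), Z=np.eye(2), groups=np.array([0, 1]),
        ))
        gw = compute_group_weights(pr.feature_weights, pr.groups, pr.n_groups)
        st, diag = solve_single(
            pr, gw, 1.0, 1.0, CoefficientState(np.zeros(0), np.zeros(2)),
            tight_hp(1.0),
        )
        np.testing.assert_allclose(st.u, [1.0, 0.0], atol=1e-9)
        assert diag.converged

    def test_above_lambda_max_returns_baseline(self, rng):
        pr, gw = make_random_problem(rng)
        b0, r0 = unpenalized_baseline(pr)
        lam_max = compute_lambda_max(pr, gw, 0.95, r0=r0)
        st, diag = solve_single(
            pr, gw, lam_max * 1.01, 0.95,
            CoefficientState(np.zeros(pr.q), np.zeros(pr.p)), tight_hp(0.95),
        )
        np.testing.assert_array_equal(st.u, 0.0)
        np.testing.assert_allclose(st.b, b0, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.95, 1.0])
    def test_matches_independent_convex_minimizer(self, rng, alpha):
        pr, gw = make_random_problem(rng, n=20, p=10, L=3)
        lam = 0.3 * compute_lambda_max(pr, gw, alpha)
        st, diag = solve_single(
            pr, gw, lam, alpha,
            CoefficientState(np.zeros(pr.q), np.zeros(pr.p)), tight_hp(alpha),
        )
        f_mine = evaluate_objective(pr, gw, st, lam, alpha)
        *_, f_oracle = solve_oracle(
            pr.y, pr.X, pr.Z, pr.groups, pr.feature_weights, gw.omega,
            lam, alpha,
        )
        assert abs(f_mine - f_oracle) <= 1e-6 * abs(f_oracle)
        assert diag.kkt_residual < 1e-5

    def test_objective_trace_nonincreasing(self, rng):
        pr, gw = make_random_problem(rng, n=15, p=8, L=3)
        lam = 0.1 * compute_lambda_max(pr, gw, 0.5)
        _, diag = solve_single(
            pr, gw, lam, 0.5,
            CoefficientState(np.zeros(pr.q), np.zeros(pr.p)),
            Hyperparameters(alpha=0.5, eps_rel=1e-8, max_iter=5000),
        )
        assert np.all(np.diff(diag.objective_trace) <= 1e-12)

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        pr, gw = make_random_problem(rng, n=15, p=8, L=3)
        lam = 0.01 * compute_lambda_max(pr, gw, 0.5)
        _, diag = solve_single(
            pr, gw, lam, 0.5,
            CoefficientState(np.zeros(pr.q), np.zeros(pr.p)),
            Hyperparameters(alpha=0.5, eps_rel=1e-14, max_iter=3),
        )
        assert not diag.converged
        assert diag.iterations == 3

    def test_at_least_one_iteration_from_optimum(self, rng):
        pr, gw = make_random_problem(rng)
        lam = 0.3 * compute_lambda_max(pr, gw, 0.95)
        hp = tight_hp(0.95)
        st, _ = solve_single(
            pr, gw, lam, 0.95,
            CoefficientState(np.zeros(pr.q), np.zeros(pr.p)), hp,
        )
        st2, diag2 = solve_single(pr, gw, lam, 0.95, st, hp)
        assert diag2.iterations >= 1
        assert diag2.converged


class TestKktResidual:
    def test_small_at_solution_large_after_perturbation(self, rng):
        pr, gw = make_random_problem(rng, n=20, p=10, L=3)
        alpha = 0.5
        lam = 0.2 * compute_lambda_max(pr, gw, alpha)
        st, _ = solve_single(
            pr, gw, lam, alpha,
            CoefficientState(np.zeros(pr.q), np.zeros(pr.p)), tight_hp(alpha),
        )
        assert kkt_residual(pr, gw, st, lam, alpha) < 1e-6
        active = np.flatnonzero(st.u)
        assert active.size > 0
        bad = st.copy()
        bad.u[active[0]] += 0.1
        assert kkt_residual(pr, gw, bad, lam, alpha) > 1e-3


class TestFitPath:
    def test_grid_length_and_zero_start(self, rng):
        pr, _ = make_random_problem(rng)
        path = fit_path(pr, Hyperparameters(n_lambda=5))
        assert len(path) == 5
        np.testing.assert_array_equal(path.states[0].u, 0.0)

    def test_sparsity_grows_down_the_path(self, rng):
        pr, _ = make_random_problem(rng, n=30, p=12, L=4, with_x=False)
        path = fit_path(pr, Hyperparameters(n_lambda=20, eps_rel=1e-6,
                                            max_iter=5000))
        nz = path.nonzero_counts()
        assert nz[0] == 0
        assert nz[-1] == nz.max() > 0

    def test_warm_equals_cold_start_per_lambda(self, rng):
        pr, gw = make_random_problem(rng, n=25, p=10, L=3)
        hp = Hyperparameters(alpha=0.95, n_lambda=10, xi=0.01,
                             eps_rel=1e-9, max_iter=50000)
        path = fit_path(pr, hp)
        for lam, st in zip(path.grid.values, path.states):
            cold, _ = solve_single(
                pr, gw, float(lam), hp.alpha,
                CoefficientState(np.zeros(pr.q), np.zeros(pr.p)), hp,
            )
            f_warm = evaluate_objective(pr, gw, st, float(lam), hp.alpha)
            f_cold = evaluate_objective(pr, gw, cold, float(lam), hp.alpha)
            assert abs(f_warm - f_cold) <= 1e-5 * abs(f_cold)

    def test_lasso_path_matches_coordinate_descent_oracle(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        pr, gw = make_random_problem(rng, n=30, p=10, L=3, with_x=False)
        hp = Hyperparameters(alpha=1.0, n_lambda=8, xi=0.05,
                             eps_rel=1e-9, max_iter=50000)
        path = fit_path(pr, hp)
        for lam, st in zip(path.grid.values, path.states):
            las = sklearn.Lasso(alpha=float(lam), fit_intercept=False,
                                tol=1e-12, max_iter=100000)
            las.fit(pr.Z, pr.y)
            ref = CoefficientState(np.zeros(0), las.coef_)
            f_mine = evaluate_objective(pr, gw, st, float(lam), 1.0)
            f_ref = evaluate_objective(pr, gw, ref, float(lam), 1.0)
            assert abs(f_mine - f_ref) <= 1e-5 * abs(f_ref)
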