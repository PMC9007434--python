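"""Two-step partially penalized estimation: projection, Lasso step,
closed-form theta recovery, limits, and the joint-objective equivalence."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mrpleio import (
    SummaryData,
    fit_reg,
    ivw,
    joint_objective,
    lambda_grid,
    lasso_delta,
    mv_ivw,
    post_reg,
    projection,
    reg_path,
    theta_from_delta,
)
from mrpleio.regularize import _scales, _working
from conftest import make_summary


def solve_joint_qp(data, lam, penalty_weights):
    """Independent generic solve of the joint partially penalized objective.

    Splits delta into positive and negative parts, making the objective a
    smooth quadratic over (theta, d+, d-) with nonnegativity bounds, and
    minimizes it with L-BFGS-B.  Entirely independent of the coordinate
    descent + closed-form path it is used to check.
    """
    w = data.weights
    k = data.k
    pw = np.asarray(penalty_weights, float)

    def fun(z):
        theta, dp, dm = z[0], z[1 : 1 + k], z[1 + k :]
        d = dp - dm
        r = data.beta_y - theta * data.beta_x - data.beta_w @ d
        wr = w * r
        obj = 0.5 * (r @ wr) / data.p + lam * (pw @ (dp + dm))
        g_theta = -(data.beta_x @ wr) / data.p
        g_d = -(data.beta_w.T @ wr) / data.p
        return obj, np.concatenate([[g_theta], g_d + lam * pw, -g_d + lam * pw])

    z0 = np.zeros(1 + 2 * k)
    bounds = [(None, None)] + [(0.0, None)] * (2 * k)
    res = minimize(
        fun, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-14},
    )
    theta = res.x[0]
    delta = res.x[1 : 1 + k] - res.x[1 + k :]
    return theta, delta, res.fun


class TestProjection:
    def test_symmetric_idempotent(self, toy_data):
        P = projection(toy_data).matrix
        np.testing.assert_allclose(P, P.T, atol=1e-12)
        np.testing.assert_allclose(P @ P, P, atol=1e-12)
        assert np.linalg.matrix_rank(P) == toy_data.p - 1

    def test_annihilates_weighted_instrument(self, toy_data):
        P = projection(toy_data).matrix
        b = toy_data.beta_x / toy_data.se_y
        np.testing.assert_allclose(P @ b, 0.0, atol=1e-12)

    def test_hand_evaluated_toy(self):
        data = SummaryData(
            variant_ids=["a", "b", "c"],
            beta_x=[1.0, 0.0, 0.0],
            beta_w=np.zeros((3, 1)),
            beta_y=[0.1, 0.2, 0.3],
            se_y=[1.0, 1.0, 1.0],
            covariate_names=["w0"],
        )
        np.testing.assert_allclose(
            projection(data).matrix, np.diag([0.0, 1.0, 1.0]), atol=1e-14
        )


class TestLassoStep:
    def test_zero_at_and_above_lambda_max(self, toy_data):
        grid = lambda_grid(toy_data)
        assert not np.any(lasso_delta(toy_data, grid[0]))
        assert not np.any(lasso_delta(toy_data, grid[0] * 1.01))

    def test_unpenalized_limit_matches_mv_ivw(self):
        data = make_summary(p=12, k=3, seed=6, noise=1.0)
        delta0 = lasso_delta(data, 0.0)
        full = mv_ivw(data)
        np.testing.assert_allclose(delta0, full.delta_hat, atol=1e-8)

    @pytest.mark.parametrize("standardize", [True, False])
    def test_convex_oracle_at_interior_lambdas(self, standardize):
        """Step-1 solution attains the generic-solver objective value."""
        data = make_summary(p=15, k=4, seed=13, noise=2.0)
        grid = lambda_grid(data, standardize=standardize)
        _, xtil = _working(data)
        pw = _scales(xtil, standardize) if standardize else np.ones(data.k)
        for lam in grid[[10, 40, 70]]:
            delta = lasso_delta(data, lam, standardize=standardize)
            theta = theta_from_delta(data, delta)
            ours = joint_objective(data, theta, delta, lam, penalty_weights=pw)
            _, _, ref = solve_joint_qp(data, lam, pw)
            assert ours <= ref + 1e-6 * max(1.0, abs(ref))


class TestThetaRecovery:
    def test_zero_delta_is_ivw(self, toy_data):
        assert theta_from_delta(toy_data, np.zeros(toy_data.k)) == pytest.approx(
            ivw(toy_data).theta_hat, rel=1e-12
        )

    def test_exact_correction(self):
        rng = np.random.default_rng(4)
        p, k = 10, 3
        beta_x = rng.uniform(0.1, 0.3, p)
        beta_w = rng.uniform(-0.2, 0.4, (p, k))
        delta = np.array([0.2, 0.0, -0.15])
        data = SummaryData(
            variant_ids=[f"v{i}" for i in range(p)],
            beta_x=beta_x,
            beta_w=beta_w,
            beta_y=0.3 * beta_x + beta_w @ delta,
            se_y=rng.uniform(0.1, 0.4, p),
            covariate_names=[f"w{j}" for j in range(k)],
        )
        assert theta_from_delta(data, delta) == pytest.approx(0.3, abs=1e-12)

    def test_closed_form_arithmetic(self, toy_data):
        delta = np.array([0.1, -0.2, 0.05])
        w = toy_data.se_y**-2.0
        corrected = toy_data.beta_y - toy_data.beta_w @ delta
        expected = (w * toy_data.beta_x) @ corrected / ((w * toy_data.beta_x) @ toy_data.beta_x)
        assert theta_from_delta(toy_data, delta) == pytest.approx(expected, rel=1e-12)


class TestJointFit:
    def test_full_shrinkage_limit_is_ivw(self, toy_data):
        grid = lambda_grid(toy_data)
        fit = fit_reg(toy_data, grid[0])
        assert fit.theta_hat == pytest.approx(ivw(toy_data).theta_hat, abs=1e-8)
        assert fit.selected == ()

    def test_no_shrinkage_limit_is_mv_all(self):
        data = make_summary(p=10, k=3, seed=21, noise=1.0)
        fit = fit_reg(data, 0.0)
        full = mv_ivw(data)
        assert fit.theta_hat == pytest.approx(full.theta_hat, abs=1e-8)
        np.testing.assert_allclose(fit.delta_hat, full.delta_hat, atol=1e-8)

    def test_two_step_equals_joint_minimizer(self):
        """Two-step (theta, delta) minimizes the joint objective: matches the
        generic convex solve and beats random perturbations."""
        rng = np.random.default_rng(0)
        data = make_summary(p=20, k=5, seed=30, noise=2.0)
        grid = lambda_grid(data)
        _, xtil = _working(data)
        pw = _scales(xtil, True)
        for lam in grid[[15, 35, 55, 75, 95]]:
            fit = fit_reg(data, lam)
            ours = joint_objective(data, fit.theta_hat, fit.delta_hat, lam, penalty_weights=pw)
            _, _, ref = solve_joint_qp(data, lam, pw)
            assert ours <= ref + 1e-6 * max(1.0, abs(ref))
            for _ in range(200):
                dt = fit.theta_hat + 0.01 * rng.standard_normal()
                dd = fit.delta_hat + 0.01 * rng.standard_normal(data.k)
                assert joint_objective(data, dt, dd, lam, penalty_weights=pw) >= ours - 1e-12

    def test_path_limits_and_l1_monotonicity(self):
        data = make_summary(p=14, k=4, seed=44, noise=1.5)
        rp = reg_path(data)
        assert not np.any(rp.delta_path[:, 0])
        assert rp.theta_path[0] == pytest.approx(ivw(data).theta_hat, abs=1e-8)
        l1 = np.abs(rp.delta_path).sum(axis=0)
        assert np.all(np.diff(l1) >= -1e-8)  # nondecreasing as lambda falls
        assert rp.active_sets[0] == ()


class TestPostReg:
    def test_empty_selection_equals_ivw(self, toy_data):
        grid = lambda_grid(toy_data)
        fit = post_reg(toy_data, grid[0])
        ref = ivw(toy_data)
        assert fit.theta_hat == ref.theta_hat
        assert fit.se_theta == ref.se_theta
        assert fit.method == "Post-reg"
        assert fit.selected == ()

    def test_oracle_selection_on_noiseless_data(self):
        data = make_summary(p=12, k=3, seed=3, theta=0.25, noise=0.0)
        grid = lambda_grid(data)
        fit = post_reg(data, grid[25])
        if fit.selected == (0,):  # true support
            assert fit.theta_hat == pytest.approx(0.25, abs=1e-8)

    def test_compositional_equality_with_mv_ivw(self):
        data = make_summary(p=16, k=4, seed=50, noise=1.0)
        lam = lambda_grid(data)[40]
        delta = lasso_delta(data, lam)
        support = tuple(np.flatnonzero(delta).tolist())
        fit = post_reg(data, lam)
        assert fit.selected == support
        if support:
            ref = mv_ivw(data, list(support))
            assert fit.theta_hat == pytest.approx(ref.theta_hat, rel=1e-12)
            np.testing.assert_allclose(fit.delta_hat, ref.delta_hat, rtol=1e-10)


def test_support_recovery_with_strong_pleiotropy():
    """With strong pleiotropic effects (all |delta_j| >= 0.2) the CV-selected
    support contains the true support in at least 90% of replicates."""
    import warnings

    from mrpleio import cv_lambda, scenario_preset, simulate_summary

    cfg = scenario_preset(1, 0.2, 2, delta_range=(0.2, 0.3))
    hits = 0
    n_rep = 200
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_rep):
            data, params, _ = simulate_summary(cfg, rng=5000 + rep)
            cv = cv_lambda(data, K=10, seed=rep)
            delta = lasso_delta(data, cv.lambda_min)
            if set(params.pleiotropic) <= set(np.flatnonzero(delta)):
                hits += 1
    assert hits / n_rep >= 0.90


def test_equivalence_over_many_random_instances():
    """Two-step solution attains the joint objective of the generic convex
    solver across a spread of instance shapes and penalties."""
    rng = np.random.default_rng(123)
    for trial in range(12):
        p = int(rng.integers(8, 26))
        k = int(rng.integers(2, min(7, p - 1)))
        data = make_summary(p=p, k=k, seed=1000 + trial, noise=float(rng.uniform(0.2, 3.0)))
        grid = lambda_grid(data)
        _, xtil = _working(data)
        pw = _scales(xtil, True)
        for lam in grid[[20, 50, 80]]:
            fit = fit_reg(data, lam)
            ours = joint_objective(data, fit.theta_hat, fit.delta_hat, lam, penalty_weights=pw)
            _, _, ref = solve_joint_qp(data, lam, pw)
            assert ours <= ref + 1e-6 * max(1.0, abs(ref))
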