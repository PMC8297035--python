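"""OLS, GWR, WTLS and GWTLSR estimators and their reduction relationships."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from gwtls import (
    ConvergenceWarning,
    DesignSystem,
    SchemaError,
    SingularSystemError,
    ValidationError,
    gwr_fit,
    gwtlsr_fit,
    ols_fit,
    predict,
    wtls_fit,
)
from conftest import make_system


def profiled_objective(x, A, y, qa, qy):
    """Independent oracle: observation-space form of the WTLS objective.

    Eliminating the design errors at their optimum leaves
    phi(x) = (y - Ax)^T [Q_y + sum_j x_j^2 diag(qa_j)]^{-1} (y - Ax).
    """
    qyt = qy + qa @ (x * x)
    r = y - A @ x
    return float(r @ (r / qyt))


def brute_force_wtls(system, starts=((0, 0), (1, 1), (-1, -1), (2, -2), (-2, 2))):
    """Grid of starts + Nelder-Mead refinement of the profiled objective."""
    A, y, qa, qy = system.A, system.y, system.qa_variances, system.qy
    best = None
    for s in starts:
        res = minimize(
            profiled_objective, np.asarray(s, float), args=(A, y, qa, qy),
            method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14, maxiter=5000),
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, best.fun


class TestDesignSystem:
    def test_validation_lists_all_problems(self):
        with pytest.raises(ValidationError) as exc:
            DesignSystem(
                A=np.ones((3, 3)),
                y=np.zeros(2),
                qa_variances=np.full((3, 3), -1.0),
                qy=np.zeros(3),
                coords=np.zeros((3, 2)),
            )
        msg = str(exc.value)
        assert "outnumber" in msg and "qy" in msg

    def test_intercept_variance_must_be_zero(self):
        with pytest.raises(ValidationError, match="intercept"):
            DesignSystem(
                A=np.column_stack([np.arange(4.0), np.ones(4)]),
                y=np.zeros(4),
                qa_variances=np.full((4, 2), 0.1),
                qy=np.ones(4),
                coords=np.zeros((4, 2)),
            )

    def test_from_features_appends_trailing_intercept(self):
        system = make_system(m=6, k=2, seed=0)
        assert np.all(system.A[:, -1] == 1.0)
        assert np.all(system.qa_variances[:, -1] == 0.0)


class TestOLS:
    @pytest.mark.parametrize(
        "x_col, y, expected",
        [
            # exact line y = x + 1
            ([1, 2, 3], [2, 3, 4], (1.0, 1.0)),
            # hand-solved 2x2 normal equations: slope 1.5, intercept -0.5
            ([0, 1, 2], [0, 0, 3], (1.5, -0.5)),
        ],
    )
    def test_known_solutions(self, x_col, y, expected):
        system = DesignSystem.from_features(
            np.asarray(x_col, float)[:, None], y, np.zeros((3, 2))
        )
        fit = ols_fit(system)
        assert fit.x_hat == pytest.approx(expected, abs=1e-12)

    def test_exact_line_has_zero_residuals(self):
        system = DesignSystem.from_features(
            np.array([[1.0], [2.0], [3.0]]), [2, 3, 4], np.zeros((3, 2))
        )
        assert ols_fit(system).residuals == pytest.approx([0, 0, 0], abs=1e-12)

    def test_intercept_only_gives_mean(self):
        y = np.array([4.0, -1.0, 2.5, 7.0])
        system = DesignSystem(
            A=np.ones((4, 1)), y=y, qa_variances=np.zeros((4, 1)),
            qy=np.ones(4), coords=np.zeros((4, 2)),
        )
        assert ols_fit(system).x_hat[0] == pytest.approx(y.mean())

    def test_rank_deficiency_names_offending_columns(self):
        X = np.zeros((6, 2))
        X[:, 0] = np.arange(6.0)
        X[:, 1] = 2 * X[:, 0]  # duplicate direction
        system = DesignSystem.from_features(
            X, np.arange(6.0), np.zeros((6, 2)), feature_names=["a", "dup_a"]
        )
        with pytest.raises(SingularSystemError) as exc:
            ols_fit(system)
        assert exc.value.columns  # at least one column identified
        assert set(exc.value.columns) <= {"a", "dup_a", "intercept"}


class TestGWR:
    def test_huge_bandwidth_reduces_to_ols(self, small_system):
        ols = ols_fit(small_system)
        gw = gwr_fit(small_system, bandwidth=1e9)
        for i in range(small_system.m):
            assert np.allclose(gw.local_coefficient(i), ols.x_hat, atol=1e-8)
        assert np.allclose(gw.fitted, ols.fitted, atol=1e-8)

    def test_two_clusters_recover_local_lines(self):
        # cluster A: y = 2x + 1 at the origin; cluster B: y = -x + 5 far away
        rng = np.random.default_rng(1)
        xa = rng.normal(0, 1, 10)
        xb = rng.normal(0, 1, 10)
        X = np.concatenate([xa, xb])[:, None]
        y = np.concatenate([2 * xa + 1, -xb + 5])
        coords = np.vstack(
            [np.tile([0.0, 0.0], (10, 1)), np.tile([1e6, 1e6], (10, 1))]
        ) + rng.normal(0, 1.0, (20, 2))
        system = DesignSystem.from_features(X, y, coords)
        gw = gwr_fit(system, bandwidth=100.0, regression_points=[[0, 0], [1e6, 1e6]])

        sys_a = DesignSystem.from_features(xa[:, None], 2 * xa + 1, coords[:10])
        sys_b = DesignSystem.from_features(xb[:, None], -xb + 5, coords[10:])
        assert np.allclose(gw.local_coefficient(0), ols_fit(sys_a).x_hat, atol=1e-6)
        assert np.allclose(gw.local_coefficient(1), ols_fit(sys_b).x_hat, atol=1e-6)

    def test_single_point_matches_weighted_normal_equations(self, small_system):
        target = np.array([300.0, 700.0])
        gw = gwr_fit(small_system, bandwidth=400.0, regression_points=[target])
        # brute-force weighted normal equations
        d = np.hypot(*(small_system.coords - target).T)
        w = np.exp(-(d**2) / 400.0**2)
        A, y = small_system.A, small_system.y
        x_direct = np.linalg.solve(A.T @ np.diag(w) @ A, A.T @ np.diag(w) @ y)
        assert np.allclose(gw.local_coefficient(0), x_direct, atol=1e-10)

    def test_unsupported_regression_point_raises_with_location(self, small_system):
        with pytest.raises(SingularSystemError) as exc:
            gwr_fit(small_system, bandwidth=1.0, regression_points=[[1e9, 1e9]])
        assert exc.value.location == (1e9, 1e9)

    def test_invalid_bandwidth(self, small_system):
        with pytest.raises(ValidationError):
            gwr_fit(small_system, bandwidth=0.0)


class TestWTLS:
    def test_zero_design_variance_unit_qy_is_ols(self, small_system):
        ols = ols_fit(small_system)
        fit = wtls_fit(small_system)
        assert np.allclose(fit.x_hat, ols.x_hat, atol=1e-10)
        assert np.all(fit.E_A_tilde == 0.0)
        assert fit.objective == pytest.approx(np.sum(ols.residuals**2), rel=1e-12)

    def test_matches_brute_force_minimizer_m4(self):
        system = make_system(m=4, k=1, seed=17, qa_scale=0.04)
        fit = wtls_fit(system, max_iter=2000)
        x_star, f_star = brute_force_wtls(system)
        assert np.allclose(fit.x_hat, x_star, atol=1e-6)
        assert fit.objective == pytest.approx(f_star, abs=1e-6)

    def test_exact_data_gives_zero_objective(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (8, 2))
        x_true = np.array([2.0, -1.0])
        y = X @ x_true + 0.5
        system = DesignSystem.from_features(
            X, y, rng.uniform(0, 10, (8, 2)), feature_variances=np.full((8, 2), 0.1)
        )
        fit = wtls_fit(system)
        assert np.allclose(fit.x_hat, [2.0, -1.0, 0.5], atol=1e-8)
        assert fit.objective == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("seed", range(6))
    def test_never_worse_than_ols_start(self, seed):
        system = make_system(m=10, k=2, seed=seed, qa_scale=0.05)
        ols = ols_fit(system)
        start_obj = profiled_objective(
            np.zeros(3) + ols.x_hat, system.A, system.y,
            np.zeros_like(system.qa_variances), system.qy,
        )  # Eq-style objective at the OLS init (no design errors yet)
        fit = wtls_fit(system, max_iter=2000)
        assert fit.objective <= start_obj + 1e-12
        assert fit.objective >= 0.0

    def test_intercept_design_error_column_is_zero(self, eiv_system):
        fit = wtls_fit(eiv_system)
        assert np.all(fit.E_A_tilde[:, -1] == 0.0)

    def test_honest_convergence_flag_and_warning(self, eiv_system):
        with pytest.warns(ConvergenceWarning):
            fit = wtls_fit(eiv_system, tol=1e-15, max_iter=1)
        assert not fit.converged
        assert fit.iterations == 1


class TestGWTLSR:
    def test_zero_design_variance_reduces_to_gwr(self, small_system):
        gw = gwr_fit(small_system, bandwidth=600.0)
        gt = gwtlsr_fit(small_system, bandwidth=600.0)
        for i in range(small_system.m):
            assert np.allclose(gt.local_coefficient(i), gw.local_coefficient(i), atol=1e-8)
        assert np.allclose(gt.fitted, gw.fitted, atol=1e-8)

    def test_double_reduction_to_ols(self, small_system):
        ols = ols_fit(small_system)
        gt = gwtlsr_fit(small_system, bandwidth=1e9)
        for i in range(small_system.m):
            assert np.allclose(gt.local_coefficient(i), ols.x_hat, atol=1e-8)

    def test_intercept_error_column_zero_everywhere(self, eiv_system):
        gt = gwtlsr_fit(eiv_system, bandwidth=500.0)
        for loc in gt.locals:
            assert np.all(loc.E_A_tilde[:, -1] == 0.0)

    def test_one_shot_mode_close_to_iterated(self, eiv_system):
        full = gwtlsr_fit(eiv_system, bandwidth=800.0, mode="iterate")
        once = gwtlsr_fit(eiv_system, bandwidth=800.0, mode="one_shot")
        # the single correction is the first step of the full cycle: close,
        # not identical
        assert np.allclose(once.coefficient_table(), full.coefficient_table(), atol=0.1)

    def test_consistency_noise_ladder(self):
        """Coefficient error shrinks monotonically as all noise scales to 0.

        One fixed noise pattern is scaled down, so the comparison is
        deterministic rather than statistical.
        """
        rng = np.random.default_rng(21)
        m, k = 30, 2
        X_true = rng.normal(0, 2, (m, k))
        coords = rng.uniform(0, 100, (m, 2))
        x_true = np.array([1.2, -0.8, 2.0])
        noise_X = rng.normal(0, 1, (m, k))
        noise_y = rng.normal(0, 1, m)
        errors = []
        for scale in (0.4, 0.2, 0.1, 0.05, 0.0):
            X_obs = X_true + scale * noise_X
            y = X_true @ x_true[:2] + x_true[2] + scale * noise_y
            system = DesignSystem.from_features(
                X_obs, y, coords, feature_variances=np.full((m, k), scale**2 + 0.0)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                fit = wtls_fit(system, max_iter=3000)
            errors.append(np.linalg.norm(fit.x_hat - x_true))
        assert all(a >= b for a, b in zip(errors, errors[1:]))
        assert errors[-1] == pytest.approx(0.0, abs=1e-8)


class TestPredict:
    def test_refit_at_training_station_equals_fitted(self, eiv_system):
        gt = gwtlsr_fit(eiv_system, bandwidth=700.0)
        i = 4
        pred = predict(
            gt, [eiv_system.coords[i]], eiv_system.A[i, :-1][None, :], mode="refit"
        )
        assert pred[0] == pytest.approx(gt.fitted[i], abs=1e-9)

    def test_zero_covariates_predict_local_intercept(self, small_system):
        gw = gwr_fit(small_system, bandwidth=500.0)
        pt = small_system.coords[2]
        pred = predict(gw, [pt], np.zeros((1, small_system.n_features)))
        assert pred[0] == pytest.approx(gw.local_coefficient(2)[-1], abs=1e-9)

    def test_constant_surface_matches_global_line(self):
        # single global line everywhere: local prediction == global prediction
        system = make_system(m=20, k=1, seed=2)
        ols = ols_fit(system)
        gw = gwr_fit(system, bandwidth=1e9)
        new_pts = np.array([[100.0, 200.0], [900.0, 50.0]])
        X_new = np.array([[0.7], [-1.3]])
        pred = predict(gw, new_pts, X_new)
        expected = np.column_stack([X_new, np.ones(2)]) @ ols.x_hat
        assert np.allclose(pred, expected, atol=1e-7)

    def test_nearest_mode_reuses_nearest_coefficients(self, small_system):
        gw = gwr_fit(small_system, bandwidth=500.0)
        j = 7
        target = small_system.coords[j] + [0.5, -0.5]
        X_new = np.array([[1.0, -1.0]])
        pred = predict(gw, [target], X_new, mode="nearest")
        expected = np.append(X_new[0], 1.0) @ gw.local_coefficient(j)
        assert pred[0] == pytest.approx(expected, abs=1e-12)

    def test_covariate_mismatch_raises_schema_error(self, small_system):
        gw = gwr_fit(small_system, bandwidth=500.0)
        with pytest.raises(SchemaError, match="features"):
            predict(gw, [[0.0, 0.0]], np.zeros((1, 5)))
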