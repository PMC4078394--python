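"""Coordinate-descent solver, penalty bounds and path behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import csgwas as cg
from csgwas.lasso import LassoConfig, kkt_max_violation

from conftest import brute_force_lambda_max


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,lam,expected",
        [(2.0, 1.0, 1.0), (-2.0, 1.0, -1.0), (0.5, 1.0, 0.0), (0.0, 0.0, 0.0), (-1.0, 1.0, 0.0)],
    )
    def test_branches(self, z, lam, expected):
        assert cg.soft_threshold(z, lam) == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        z=st.floats(-1e6, 1e6, allow_nan=False),
        lam=st.floats(0, 1e6, allow_nan=False),
    )
    def test_shrinks_toward_zero_by_at_most_lambda(self, z, lam):
        out = cg.soft_threshold(z, lam)
        assert abs(out) == max(abs(z) - lam, 0.0)
        assert out * z >= 0.0  # never flips sign

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            cg.soft_threshold(1.0, -0.1)


class TestLambdaBounds:
    def test_lambda_max_zero_for_orthogonal_phenotype(self):
        A = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]) * np.sqrt(2)
        y = np.array([0.0, 0.0, 0.0, 0.0])
        assert cg.lambda_max(A, y) == 0.0

    def test_lambda_max_unity_for_identical_column(self, medium_genotypes):
        col = medium_genotypes.standardized[:, [0]]
        assert cg.lambda_max(col, col[:, 0]) == pytest.approx(1.0, rel=1e-12)

    def test_lambda_max_matches_brute_force(self, noisy_instance):
        gm, _, real = noisy_instance
        assert cg.lambda_max(gm, real.y) == pytest.approx(
            brute_force_lambda_max(gm.standardized, real.y), rel=1e-12
        )

    def test_lambda_min_half_normal_closed_form(self):
        # p = 1: A'e ~ N(0, n), so median |A'e| = 0.6745 sqrt(n)
        n = 400
        gm = cg.simulate_genotypes(n, 1, maf_spec=[0.3], seed=21)
        lam = cg.lambda_min_theoretical(gm, sigma_e2=0.75, n_draws=8001, seed=22)
        sigma_star = np.sqrt(0.75 + 1 / n)
        expected = sigma_star * 0.674490 * np.sqrt(n) / n
        assert lam == pytest.approx(expected, rel=0.05)

    def test_lambda_min_deterministic_in_seed(self, medium_genotypes):
        a = cg.lambda_min_theoretical(medium_genotypes, 0.5, n_draws=50, seed=3)
        b = cg.lambda_min_theoretical(medium_genotypes, 0.5, n_draws=50, seed=3)
        assert a == b

    def test_lambda_min_vanishes_with_noise_and_n(self):
        # sigma_E* = sqrt(0 + 1/n) -> 0, so the bound shrinks as n grows
        lams = [
            cg.lambda_min_theoretical(
                cg.simulate_genotypes(n, 5, seed=23), 0.0, n_draws=100, seed=24
            )
            for n in (100, 1000, 10_000)
        ]
        assert lams[0] > lams[1] > lams[2]


class TestCoordinateDescent:
    def test_penalty_at_lambda_max_returns_zero(self, noisy_instance):
        gm, _, real = noisy_instance
        lam = cg.lambda_max(gm, real.y)
        x, _, ok = cg.coordinate_descent(gm, real.y, lam)
        assert ok
        assert np.all(x == 0.0)

    def test_single_marker_closed_form(self, medium_genotypes):
        A = medium_genotypes.standardized[:, [7]]
        y = medium_genotypes.standardized[:, 8] * 0.5
        n = A.shape[0]
        for lam in (0.0, 0.01, 0.2):
            x, _, _ = cg.coordinate_descent(A, y, lam, tol=1e-12)
            expected = cg.soft_threshold(float(A[:, 0] @ y) / n, lam)
            assert x[0] == pytest.approx(expected, abs=1e-10)

    def test_unpenalized_overdetermined_matches_ols(self):
        gm = cg.simulate_genotypes(150, 20, seed=25)
        model = cg.make_true_model(cg.EnsembleSpec.signs(5), gm.markers, h2=0.8, seed=26)
        real = cg.simulate_phenotype(gm, model, seed=27)
        A = gm.standardized
        x, _, _ = cg.coordinate_descent(A, real.y, 0.0, tol=1e-14, max_sweeps=200_000)
        ols = np.linalg.solve(A.T @ A, A.T @ real.y)  # normal-equations oracle
        np.testing.assert_allclose(x, ols, atol=1e-6)

    def test_kkt_conditions_at_convergence(self, noisy_instance):
        gm, _, real = noisy_instance
        lam = 0.5 * cg.lambda_max(gm, real.y)
        tol = 1e-6
        x, _, ok = cg.coordinate_descent(gm, real.y, lam, tol=tol)
        assert ok
        assert kkt_max_violation(gm, real.y, x, lam) < 10 * tol

    def test_non_finite_inputs_rejected(self, small_genotypes):
        y = np.full(small_genotypes.n_subjects, np.nan)
        with pytest.raises(ValueError):
            cg.coordinate_descent(small_genotypes, y, 0.1)

    def test_active_set_matches_plain_sweeps(self, noisy_instance):
        gm, _, real = noisy_instance
        lam = 0.3 * cg.lambda_max(gm, real.y)
        xa, _, _ = cg.coordinate_descent(gm, real.y, lam, tol=1e-10, use_active_set=True)
        xp, _, _ = cg.coordinate_descent(gm, real.y, lam, tol=1e-10, use_active_set=False)
        assert cg.normalized_error(xp, xa) < 1e-4

    def test_matches_quadratic_program_oracle(self):
        # split x = u - v, u, v >= 0: the lasso objective becomes smooth + box
        from scipy import optimize

        gm = cg.simulate_genotypes(60, 100, seed=28)
        model = cg.make_true_model(cg.EnsembleSpec.signs(5), gm.markers, h2=0.6, seed=29)
        real = cg.simulate_phenotype(gm, model, seed=30)
        A, y = gm.standardized, real.y
        n, p = A.shape
        lam = 0.4 * cg.lambda_max(A, y)

        def fun(uv):
            u, v = uv[:p], uv[p:]
            r = y - A @ (u - v)
            grad_x = -(A.T @ r) / n
            f = 0.5 / n * (r @ r) + lam * (u.sum() + v.sum())
            return f, np.concatenate([grad_x + lam, -grad_x + lam])

        res = optimize.minimize(
            fun, np.zeros(2 * p), jac=True, method="L-BFGS-B",
            bounds=[(0, None)] * (2 * p),
            options={"maxiter": 20_000, "ftol": 1e-16, "gtol": 1e-12},
        )
        x_qp = res.x[:p] - res.x[p:]
        x_cd, _, _ = cg.coordinate_descent(A, y, lam, tol=1e-12)
        assert cg.normalized_error(x_qp, x_cd) < 1e-4


class TestPath:
    def test_first_grid_point_is_zero_and_objective_descends(self, noisy_instance):
        gm, model, real = noisy_instance
        cfg = LassoConfig(sigma_e2=0.5, n_noise_draws=200, seed=31)
        path = cg.lasso_path(gm, real.y, cfg)
        assert np.all(path.coefficients[0] == 0.0)
        assert np.all(np.diff(path.lambdas) < 0)
        assert len(path.lambdas) == cfg.n_lambda_steps
        # terminal objective beats the zero vector at the terminal penalty
        n = gm.n_subjects
        f_zero = 0.5 / n * float(real.y @ real.y)
        assert path.objective[-1] <= f_zero

    def test_noiseless_recovery_phase(self):
        gm = cg.simulate_genotypes(500, 1000, seed=32)
        model = cg.make_true_model(cg.EnsembleSpec.signs(10), gm.markers, h2=1.0, seed=33)
        real = cg.simulate_phenotype(gm, model, seed=34)
        path = cg.lasso_path(gm, real.y, LassoConfig(sigma_e2=0.0, n_noise_draws=200, seed=35))
        assert cg.normalized_error(real.x, path.terminal) < 0.05

    def test_warm_start_matches_cold_start(self):
        gm = cg.simulate_genotypes(200, 400, seed=36)
        model = cg.make_true_model(cg.EnsembleSpec.signs(8), gm.markers, h2=0.5, seed=37)
        real = cg.simulate_phenotype(gm, model, seed=38)
        cfg = LassoConfig(sigma_e2=0.5, n_lambda_steps=20, tol=1e-9, n_noise_draws=200, seed=39)
        path = cg.lasso_path(gm, real.y, cfg)
        for k in (5, 12, 19):
            cold, _, _ = cg.coordinate_descent(
                gm, real.y, float(path.lambdas[k]), tol=1e-9
            )
            if np.any(cold):
                assert cg.normalized_error(cold, path.coefficients[k]) < 1e-4

    def test_degenerate_grid_returns_zero_path_with_warning(self, small_genotypes):
        rng = np.random.default_rng(0)
        y = np.zeros(small_genotypes.n_subjects)  # lambda_max = 0
        with pytest.warns(UserWarning, match="all-zero path"):
            path = cg.lasso_path(
                small_genotypes, y, LassoConfig(sigma_e2=1.0, n_noise_draws=50, seed=40)
            )
        assert np.all(path.coefficients == 0.0)

    def test_select_extracts_terminal_support(self, noisy_instance):
        gm, _, real = noisy_instance
        path = cg.lasso_path(gm, real.y, LassoConfig(sigma_e2=0.5, n_noise_draws=200, seed=41))
        sel = cg.select(path)
        np.testing.assert_array_equal(sel.support, np.flatnonzero(path.terminal))

    def test_stricter_terminal_penalty_selects_no_more(self, noisy_instance):
        # a penalty set for lower assumed noise reaches deeper; the stricter
        # (higher) terminal penalty selects a smaller-or-equal support here
        gm, _, real = noisy_instance
        loose = cg.lasso_path(gm, real.y, LassoConfig(sigma_e2=0.25, n_noise_draws=200, seed=42))
        strict = cg.lasso_path(gm, real.y, LassoConfig(sigma_e2=0.9, n_noise_draws=200, seed=42))
        assert np.count_nonzero(strict.terminal) <= np.count_nonzero(loose.terminal)


class TestCrossValidation:
    def test_fold_assignment_deterministic(self, noisy_instance):
        gm, _, real = noisy_instance
        cfg = LassoConfig(sigma_e2=0.5, n_lambda_steps=15, n_noise_draws=100, seed=43)
        a, _ = cg.cv_lambda(gm, real.y, k=5, config=cfg, seed=44)
        b, _ = cg.cv_lambda(gm, real.y, k=5, config=cfg, seed=44)
        assert a == b

    def test_pure_noise_selects_heavy_penalty(self):
        gm = cg.simulate_genotypes(200, 100, seed=45)
        cfg = LassoConfig(sigma_e2=1.0, n_lambda_steps=20, n_noise_draws=100, seed=46)
        chosen = []
        for r in range(10):
            y = np.random.default_rng(4700 + r).standard_normal(200)
            lam, _ = cg.cv_lambda(gm, y, k=5, config=cfg, seed=48)
            grid = np.geomspace(
                cg.lambda_max(gm, y),
                min(cg.lambda_min_theoretical(gm, 1.0, 100, 46), cg.lambda_max(gm, y) * 0.999),
                20,
            )
            chosen.append(np.searchsorted(-grid, -lam))  # index on the descending grid
        assert np.median(chosen) < 5  # top quartile of the 20-point grid

    def test_strong_signal_selects_light_penalty(self):
        gm = cg.simulate_genotypes(300, 100, seed=49)
        model = cg.make_true_model(cg.EnsembleSpec.signs(10), gm.markers, h2=1.0, seed=50)
        real = cg.simulate_phenotype(gm, model, seed=51)
        cfg = LassoConfig(sigma_e2=0.0, n_lambda_steps=20, n_noise_draws=100, seed=52)
        lam, _ = cg.cv_lambda(gm, real.y, k=5, config=cfg, seed=53)
        lam_max = cg.lambda_max(gm, real.y)
        assert lam < lam_max * 0.1  # bottom half of the log grid

    def test_too_few_subjects_rejected(self, small_genotypes):
        y = np.zeros(small_genotypes.n_subjects)
        with pytest.raises(ValueError):
            cg.cv_lambda(small_genotypes, y, k=small_genotypes.n_subjects + 1)
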