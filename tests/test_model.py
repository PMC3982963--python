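"""Tests for GBLUP, marker ridge, PEV/reliability and related algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgblup import (GBLUP, MarkerMatrix, MarkerRidge, VarianceComponents,
                    build_grm, fit_gblup, hat_matrix, ols_effects,
                    prediction_error_covariance, predictive_correlation_bound,
                    ridge_marker_blup)
from bgblup.exceptions import (AlignmentError, EstimabilityError,
                               ParameterError, SolverError)


class TestMarkerMatrix:
    def test_centering_is_idempotent(self, rng):
        M = MarkerMatrix(rng.random((5, 3)))
        C = M.center()
        assert C.center() is C
        assert np.allclose(C.values.mean(axis=0), 0.0)
        assert np.allclose(C.column_means, M.values.mean(axis=0))

    def test_center_like_uses_training_means(self, rng):
        A = MarkerMatrix(rng.random((6, 3)))
        B = MarkerMatrix(rng.random((4, 3)))
        Bc = B.center_like(A)
        assert np.allclose(Bc.values, B.values - A.values.mean(axis=0))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="dup"):
            MarkerMatrix([[0.0], [1.0]], ids=["dup", "dup"])


class TestVarianceComponents:
    def test_ratio_resolution(self):
        vc = VarianceComponents(sigma2_e=10.0, sigma2_beta=2.0)
        assert vc.lam == 5.0
        with pytest.raises(ParameterError):
            VarianceComponents(sigma2_e=10.0, sigma2_beta=2.0, lam=3.0)
        with pytest.raises(ParameterError):
            VarianceComponents()
        with pytest.raises(ParameterError):
            VarianceComponents(lam=1.0, weights=[1.0, 0.0])


class TestGrm:
    def test_hand_computed_two_by_two(self):
        G = build_grm(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(G, [[0.5, -0.5], [-0.5, 0.5]])

    def test_gram_matrix_is_psd(self, rng):
        X = rng.normal(size=(30, 50))
        G = build_grm(X)
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-8 * np.trace(G)

    def test_correlation_scheme_unit_diagonal(self, rng):
        X = (rng.random((20, 40)) < 0.5).astype(float)
        C = build_grm(X, "correlation")
        assert np.allclose(np.diag(C), 1.0)
        assert np.all(np.abs(C) <= 1 + 1e-12)

    def test_zero_norm_individual_rejected_under_correlation(self):
        # one individual equal to the column means has zero centered norm
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        with pytest.raises(ParameterError, match="zero-norm"):
            build_grm(X, "correlation")


class TestGblupFit:
    def test_two_by_two_hand_solution(self):
        res = fit_gblup(np.eye(2), [2.0, -2.0], 1.0)
        assert np.allclose(res.alpha, [1.0, -1.0])
        assert np.allclose(res.ghat, [1.0, -1.0])

    def test_infinite_shrinkage_kills_fit(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        res = fit_gblup(build_grm(X), y, 1e12)
        assert np.linalg.norm(res.ghat) < 1e-6 * np.linalg.norm(y)

    def test_self_prediction_identity(self, small_xy):
        X, y, _ = small_xy
        G = build_grm(X)
        res = fit_gblup(G, y, 5.0)
        assert np.allclose(res.predict(G), res.fittedvalues)

    def test_zero_relationship_predicts_training_mean(self, small_xy):
        X, y, _ = small_xy
        res = fit_gblup(build_grm(X), y, 5.0)
        pred = res.predict(np.zeros((3, len(y))))
        assert np.allclose(pred, y.mean())

    def test_singular_system_reports_lam(self):
        G = np.zeros((3, 3))
        with pytest.raises(SolverError, match="lam=0"):
            fit_gblup(G, [1.0, 2.0, 3.0], 0.0)

    def test_misaligned_cross_matrix_rejected(self, small_xy):
        X, y, _ = small_xy
        res = fit_gblup(build_grm(X), y, 5.0)
        with pytest.raises(AlignmentError):
            res.predict(np.zeros((2, 7)))

    def test_summary_mentions_key_quantities(self, small_xy):
        X, y, _ = small_xy
        s = GBLUP.from_markers(y, X, 5.0).fit().summary()
        assert "lambda" in s and "trace(H)" in s


class TestRidge:
    def test_scalar_hand_solution(self):
        beta = ridge_marker_blup(np.array([[1.0], [-1.0]]), [1.0, -1.0], 1.0)
        assert np.allclose(beta, 2.0 / 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_primal_and_dual_routes_agree(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 200))
        y = rng.normal(size=50)
        dual = ridge_marker_blup(X, y, 7.0)          # p > n path
        Xc = X - X.mean(axis=0)
        primal = np.linalg.solve(Xc.T @ Xc + 7.0 * np.eye(200),
                                 Xc.T @ (y - y.mean()))
        assert np.allclose(dual, primal, rtol=1e-8, atol=1e-10)

    def test_matches_sklearn_ridge(self, small_xy):
        # independent oracle: scikit-learn solves the same penalized
        # least-squares problem when alpha = lam and an intercept is fit
        from sklearn.linear_model import Ridge

        X, y, _ = small_xy
        ours = ridge_marker_blup(X, y, 3.0)
        ref = Ridge(alpha=3.0, fit_intercept=True).fit(X, y).coef_
        assert np.allclose(ours, ref, atol=1e-8)

    def test_henderson_equivalence_with_gblup(self, wide_xy):
        X, y, _ = wide_xy
        beta = ridge_marker_blup(X, y, 4.0)
        res = fit_gblup(build_grm(X), y, 4.0)
        Xc = X - X.mean(axis=0)
        assert np.allclose(Xc @ beta, res.ghat, rtol=1e-8, atol=1e-9)

    def test_lam_zero_rejected(self, small_xy):
        X, y, _ = small_xy
        with pytest.raises(ParameterError):
            MarkerRidge(y, X, 0.0)

    def test_shrinkage_monotone_in_lam(self, small_xy):
        X, y, _ = small_xy
        G = build_grm(X)
        norms = [np.linalg.norm(fit_gblup(G, y, lam).ghat)
                 for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))


class TestOls:
    def test_orthonormal_design(self):
        # columns orthonormal and centered: OLS reduces to X'y
        X = np.array([[1.0, 1.0], [1.0, -1.0],
                      [-1.0, 1.0], [-1.0, -1.0]]) / 2.0
        y = np.array([1.0, 2.0, 3.0, -6.0])
        assert np.allclose(ols_effects(X, y), X.T @ y)

    def test_noiseless_recovery(self, small_xy):
        X, _, beta = small_xy
        y = X @ beta
        assert np.allclose(ols_effects(X, y), beta, atol=1e-8)

    def test_rank_deficiency_raises(self, rng):
        X = rng.normal(size=(10, 20))
        with pytest.raises(EstimabilityError, match="n=10"):
            ols_effects(X, rng.normal(size=10))
        Xd = rng.normal(size=(30, 4))
        Xd[:, 3] = Xd[:, 0]  # duplicated column
        with pytest.raises(EstimabilityError, match="rank"):
            ols_effects(Xd, rng.normal(size=30))


class TestPev:
    def test_no_information_limit(self):
        rep = prediction_error_covariance(
            np.zeros((6, 4)), VarianceComponents(sigma2_e=2.0, sigma2_beta=1.0))
        assert np.allclose(rep.pev, np.eye(4))
        assert np.allclose(rep.reliabilities, 0.0)

    def test_perfect_estimation_limit(self, small_xy):
        X, _, _ = small_xy
        rep = prediction_error_covariance(
            X, VarianceComponents(lam=1e-10), level="marker")
        assert np.all(rep.reliabilities > 1 - 1e-6)

    def test_pev_symmetric_and_reliability_bounded(self, wide_xy):
        X, _, _ = wide_xy
        rep = prediction_error_covariance(
            X, VarianceComponents(sigma2_e=6.0, sigma2_beta=2.0))
        assert np.allclose(rep.pev, rep.pev.T)
        assert np.all(rep.reliabilities <= 1.0 + 1e-12)
        assert np.all(rep.reliabilities >= 0.0 - 1e-12)

    def test_signal_level_matches_hat_diagonal(self, small_xy):
        X, y, _ = small_xy
        vc = VarianceComponents(lam=5.0)
        rep = prediction_error_covariance(X, vc, level="signal")
        H = hat_matrix(build_grm(X), vc)
        assert np.allclose(rep.reliabilities, np.diag(H))


class TestHatMatrix:
    def test_near_interpolation_at_tiny_lam(self, rng):
        A = rng.normal(size=(6, 6))
        G = A @ A.T + 6 * np.eye(6)  # strictly pd
        H = hat_matrix(G, 1e-10)
        assert np.allclose(H, np.eye(6), atol=1e-7)

    def test_dense_inverse_oracle(self, rng):
        A = rng.normal(size=(5, 5))
        G = A @ A.T
        H = hat_matrix(G, 1.0)
        ref = G @ np.linalg.inv(G + np.eye(5))
        assert np.allclose(H, ref, atol=1e-10)

    def test_effective_parameters_shrink_with_lam(self, small_xy):
        X, _, _ = small_xy
        G = build_grm(X)
        traces = [np.trace(hat_matrix(G, lam))
                  for lam in (0.5, 2.0, 10.0, 50.0, 250.0)]
        assert all(b < a for a, b in zip(traces, traces[1:]))

    def test_maps_centered_phenotypes_to_fit(self, small_xy):
        X, y, _ = small_xy
        G = build_grm(X)
        res = fit_gblup(G, y, 3.0)
        assert np.allclose(hat_matrix(G, 3.0) @ (y - y.mean()), res.ghat)


class TestPredictiveBound:
    @pytest.mark.parametrize("h2,n_bar,expect", [
        (1.0, 1, 1.0), (1.0, 50, 1.0), (0.25, 1, 0.5), (0.0, 10, 0.0)])
    def test_closed_forms(self, h2, n_bar, expect):
        assert predictive_correlation_bound(h2, n_bar) == pytest.approx(expect)

    def test_mean_of_many_records_approaches_one(self):
        b = [predictive_correlation_bound(0.25, n) for n in (1, 10, 1000)]
        assert b[0] < b[1] < b[2] < 1.0
        assert b[2] > 0.99

    def test_invalid_h2_rejected(self):
        with pytest.raises(ParameterError):
            predictive_correlation_bound(1.5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.integers(min_value=2, max_value=40),
       st.integers(min_value=1, max_value=60),
       st.floats(min_value=0.05, max_value=50.0))
def test_primal_dual_equivalence_property(seed, n, p, lam):
    """X @ ridge == GBLUP fitted signal, for arbitrary shapes and lam."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    beta = ridge_marker_blup(X, y, lam)
    res = fit_gblup(build_grm(X), y, lam)
    Xc = X - X.mean(axis=0)
    np.testing.assert_allclose(Xc @ beta, res.ghat, rtol=1e-8, atol=1e-8)
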