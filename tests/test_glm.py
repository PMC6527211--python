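"""IRLS core: likelihood, Fisher information, Wald machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

import rarepen as rp

# a fixed 6-row hand dataset used by several brute-force checks
X6 = np.array([[0.0], [0.0], [1.0], [1.0], [0.0], [1.0]])
Y6 = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 0.0])


def _design(X):
    return np.column_stack([np.ones(len(X)), X])


class TestLogLikelihood:
    def test_null_coefficients_give_n_log_half(self):
        beta = np.zeros(2)
        assert rp.log_likelihood(beta, _design(X6), Y6) == pytest.approx(
            6 * np.log(0.5))

    def test_matches_per_observation_product(self):
        beta = np.array([0.3, -0.8])
        pi = expit(_design(X6) @ beta)
        brute = float(np.log(np.prod(np.where(Y6 == 1, pi, 1 - pi))))
        assert rp.log_likelihood(beta, _design(X6), Y6) == pytest.approx(brute)

    def test_perfect_fit_limit_approaches_zero_from_below(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 1.0])
        lls = [rp.log_likelihood(np.array([-c / 2, c]), _design(X), y)
               for c in (5.0, 20.0, 60.0)]
        assert all(ll < 0 for ll in lls)
        assert lls[0] < lls[1] < lls[2] < 0
        assert lls[2] > -1e-6


def _table_data(a, b, c, d):
    """Binary predictor data for the 2x2 table [[a, b], [c, d]]."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return x[:, None], y


class TestIrls:
    @given(st.integers(3, 60), st.integers(3, 60), st.integers(3, 60),
           st.integers(3, 60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_slope_equals_table_log_odds_ratio(self, a, b, c, d):
        X, y = _table_data(a, b, c, d)
        fit = rp.irls_fit(X, y)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(
            np.log(a * d / (b * c)), abs=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        X = rng.binomial(1, [0.4, 0.2, 0.3], size=(500, 3)).astype(float)
        y = (rng.random(500) < expit(0.3 + X @ [1.0, -0.5, 0.0])).astype(float)
        ours = rp.irls_fit(X, y)
        ref = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        assert np.allclose(ours.coefficients, ref.params, atol=1e-6)
        assert np.allclose(ours.standard_errors, ref.bse, atol=1e-5)

    def test_complete_separation_flags_divergence(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = rp.irls_fit(x[:, None], y)
        assert not fit.converged
        assert fit.divergence_flags.any()

    def test_all_zero_column_flagged_for_mle(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.binomial(1, 0.4, 200), np.zeros(200)])
        y = rng.binomial(1, 0.5, 200).astype(float)
        fit = rp.irls_fit(X, y)
        assert fit.divergence_flags[2]
        assert fit.coefficients[2] == 0.0

    def test_heavy_ridge_shrinks_slopes_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(1, 0.4, size=(300, 2)).astype(float)
        y = rng.binomial(1, 0.5, 300).astype(float)
        fit = rp.irls_fit(X, y, l2=1e7)
        assert np.all(np.abs(fit.coefficients[1:]) < 1e-4)

    def test_penalized_gradient_norm_small_at_solution(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(1, [0.3, 0.1, 0.05], size=(400, 3)).astype(float)
        y = (rng.random(400) < expit(X @ [1, -1, 2.0])).astype(float)
        for l2 in (0.5, 5.0, 50.0):
            fit = rp.irls_fit(X, y, l2=l2)
            Xd = _design(X)
            pi = expit(Xd @ fit.coefficients)
            grad = Xd.T @ (y - pi)
            grad[1:] -= 2 * l2 * fit.coefficients[1:]
            assert np.max(np.abs(grad)) < 1e-6

    def test_objective_ascends_across_accepted_steps(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(1, 0.2, size=(300, 4)).astype(float)
        y = (rng.random(300) < expit(X @ [2, 0, -2, 0.0])).astype(float)
        fit = rp.irls_fit(X, y)
        trace = np.asarray(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-9)


class TestFisherInformation:
    def test_intercept_only_quarter_n(self):
        Xd = np.ones((40, 1))
        info = rp.fisher_information(np.zeros(1), Xd)
        assert info == pytest.approx(np.array([[10.0]]))

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(2)
        Xd = _design(rng.binomial(1, 0.3, size=(100, 3)).astype(float))
        info = rp.fisher_information(rng.normal(size=4), Xd)
        assert np.allclose(info, info.T)
        assert np.all(np.linalg.eigvalsh(info) > -1e-10)

    def test_agrees_with_numerical_hessian(self):
        Xd = _design(X6)
        beta = np.array([0.2, -0.4])
        info = rp.fisher_information(beta, Xd)
        eps = 1e-5
        hess = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                bpp = beta.copy(); bpp[i] += eps; bpp[j] += eps
                bpm = beta.copy(); bpm[i] += eps; bpm[j] -= eps
                bmp = beta.copy(); bmp[i] -= eps; bmp[j] += eps
                bmm = beta.copy(); bmm[i] -= eps; bmm[j] -= eps
                hess[i, j] = (rp.log_likelihood(bpp, Xd, Y6)
                              - rp.log_likelihood(bpm, Xd, Y6)
                              - rp.log_likelihood(bmp, Xd, Y6)
                              + rp.log_likelihood(bmm, Xd, Y6)) / (4 * eps**2)
        assert np.allclose(info, -hess, atol=1e-4)


class TestWald:
    def _fit(self, coefs, ses):
        return rp.LogisticFit(
            coefficients=np.asarray(coefs, float),
            standard_errors=np.asarray(ses, float),
            log_likelihood=0.0, converged=True, n_iterations=1,
            divergence_flags=np.zeros(len(coefs), bool))

    def test_zero_coefficient_gives_p_one(self):
        assert rp.wald_pvalues(self._fit([0.0], [1.0]))[0] == pytest.approx(1.0)

    def test_z_196_gives_p_half_of_five_percent_band(self):
        p = rp.wald_pvalues(self._fit([1.96], [1.0]))[0]
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_monotone_decreasing_in_z(self):
        p = rp.wald_pvalues(self._fit([0.1, 0.5, 1.0, 3.0], [1, 1, 1, 1]))
        assert np.all(np.diff(p) < 0)

    def test_missing_se_raises(self):
        fit = self._fit([1.0], [1.0])
        fit.standard_errors = None
        with pytest.raises(ValueError):
            rp.wald_pvalues(fit)
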