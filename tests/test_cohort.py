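"""Generator: prevalence grid, associations, latent-Gaussian sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rarepen as rp
from rarepen.cohort import (bivariate_normal_cdf, common_probability,
                            solve_latent_correlation)


class TestPrevalenceGrid:
    def test_endpoints_exact_and_log_even(self):
        grid = rp.make_prevalence_grid(50, 0.03, 5e-5)
        assert grid[0] == 0.03 and grid[-1] == 5e-5
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)
        assert np.all(np.diff(grid) < 0)

    def test_interior_matches_published_headers(self):
        # the relevant-variable prevalence headers 0.6%, 0.1%, 0.02%
        grid = rp.make_prevalence_grid(50, 0.03, 5e-5)
        assert np.isclose(grid[12], 0.006, rtol=0.1)
        assert np.isclose(grid[25], 0.001, rtol=0.2)
        assert np.isclose(grid[38], 0.0002, rtol=0.1)

    def test_degenerate_equal_endpoints(self):
        assert np.allclose(rp.make_prevalence_grid(2, 0.5, 0.5), [0.5, 0.5])

    @pytest.mark.parametrize("args", [(1, 0.03, 5e-5), (50, 5e-5, 0.03),
                                      (50, 1.2, 0.1), (50, 0.03, 0.0)])
    def test_invalid_bounds_rejected(self, args):
        with pytest.raises(rp.ConfigurationError):
            rp.make_prevalence_grid(*args)


class TestAssociations:
    def test_zero_exponent_gives_independence(self):
        assert common_probability(0.2, 0.1, 0.0) == pytest.approx(0.02)

    def test_clamping_at_frechet_upper_bound(self):
        # raw 0.25 * 2^2 = 1.0 exceeds min(p_i, p_j)
        assert common_probability(0.5, 0.5, 2.0) == pytest.approx(0.5)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99),
           st.floats(-6.0, 6.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_frechet_bounds_always_hold(self, pi, pj, h):
        c = float(common_probability(pi, pj, h))
        assert max(0.0, pi + pj - 1.0) - 1e-12 <= c <= min(pi, pj) + 1e-12

    def test_draw_is_reproducible_and_symmetric(self):
        p = rp.make_prevalence_grid(10, 0.3, 0.01)
        d1 = rp.draw_common_probabilities(p, seed=5)
        d2 = rp.draw_common_probabilities(p, seed=5)
        d3 = rp.draw_common_probabilities(p, seed=6)
        assert np.array_equal(d1.h, d2.h)
        assert not np.array_equal(d1.h, d3.h)
        assert np.allclose(d1.common_prob, d1.common_prob.T)


class TestLatentGaussian:
    def test_bvn_cdf_matches_scipy_orthant_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pa, pb = rng.uniform(1e-4, 0.5, 2)
            rho = rng.uniform(-0.9, 0.9)
            a, b = stats.norm.ppf([pa, pb])
            ref = stats.multivariate_normal(
                mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([a, b])
            assert bivariate_normal_cdf(a, b, rho) == pytest.approx(
                ref, rel=1e-6, abs=1e-12)

    def test_independence_target_solves_to_zero_correlation(self):
        a = stats.norm.ppf(0.3)
        rho = solve_latent_correlation(a, a, 0.09)
        assert abs(rho) < 1e-8

    def test_upper_frechet_target_gives_comonotone_columns(self):
        t = stats.norm.ppf(0.2)
        rho = float(solve_latent_correlation(t, t, 0.2))
        assert rho > 0.999
        p = np.array([0.2, 0.2])
        assoc = rp.AssociationDraw(h=np.zeros((2, 2)),
                                   common_prob=np.full((2, 2), 0.2))
        X = rp.sample_correlated_binary(p, assoc, 20000, seed=0)
        assert np.mean(X[:, 0] == X[:, 1]) > 0.999

    def test_column_prevalences_recovered_within_4_se(self):
        spec = rp.ExposureSpec.default()
        assoc = rp.draw_common_probabilities(spec.prevalences, seed=11)
        n = 100_000
        X = rp.sample_correlated_binary(spec.prevalences, assoc, n, seed=12)
        p = spec.prevalences
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(X.mean(axis=0) - p) <= 4 * se)

    def test_independent_draw_has_near_zero_correlation(self):
        p = np.full(4, 0.5)
        assoc = rp.AssociationDraw(h=np.zeros((4, 4)),
                                   common_prob=np.full((4, 4), 0.25))
        X = rp.sample_correlated_binary(p, assoc, 100_000, seed=3)
        corr = np.corrcoef(X.T)
        off = corr[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.02)

    def test_same_seed_bit_identical_different_seed_not(self):
        p = rp.make_prevalence_grid(8, 0.3, 0.05)
        assoc = rp.draw_common_probabilities(p, seed=0)
        X1 = rp.sample_correlated_binary(p, assoc, 5000, seed=9)
        X2 = rp.sample_correlated_binary(p, assoc, 5000, seed=9)
        X3 = rp.sample_correlated_binary(p, assoc, 5000, seed=10)
        assert np.array_equal(X1, X2)
        assert not np.array_equal(X1, X3)


class TestOutcomeModel:
    def test_gamma_closed_form_and_scaling(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(1, 0.5, size=(50_000, 1)).astype(np.int8)
        spec1 = rp.ExposureSpec(np.array([0.5]), (0,), (-1,))
        g1 = rp.calibrate_gamma(X, spec1, snr=3.0)
        var = X[:, 0].astype(float).var()
        assert g1 == pytest.approx(np.sqrt(var / 1.5), rel=1e-12)
        # doubling the signal (two identical effects) doubles its sd
        X2 = np.column_stack([X, X])
        spec2 = rp.ExposureSpec(np.array([0.5, 0.5]), (0, 1), (-1, -1))
        g2 = rp.calibrate_gamma(X2, spec2, snr=3.0)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_zero_signal_variance_is_a_configuration_error(self):
        X = np.zeros((100, 1), dtype=np.int8)
        spec = rp.ExposureSpec(np.array([0.5]), (0,), (1,))
        with pytest.raises(rp.ConfigurationError):
            rp.calibrate_gamma(X, spec)

    def test_outcome_probability_baseline_and_single_term(self):
        spec = rp.ExposureSpec.default()
        X = np.zeros((2, 50))
        X[1, 12] = 1  # x13 carries effect +1
        Z = np.zeros((2, 2))
        probs = rp.outcome_probability(X, Z, spec, gamma=0.0, intercept=0.0)
        assert probs[0] == pytest.approx(0.5)
        assert probs[1] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_population_outcome_prevalence_near_half(self):
        spec = rp.ExposureSpec.default()
        assoc = rp.draw_common_probabilities(spec.prevalences, seed=2)
        X = rp.sample_correlated_binary(spec.prevalences, assoc, 30_000, seed=3)
        Z = np.random.default_rng(4).binomial(1, 0.5, (30_000, 2)).astype(np.int8)
        gamma = rp.calibrate_gamma(X, spec)
        y = rp.simulate_outcome(X, Z, spec, gamma, 0.0, seed=5)
        assert abs(y.mean() - 0.5) < 0.02


class TestCaseControl:
    def _population(self, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.binomial(1, 0.2, (n, 3)).astype(np.int8)
        Z = rng.binomial(1, 0.5, (n, 2)).astype(np.int8)
        y = rng.binomial(1, 0.5, n).astype(np.int8)
        return X, Z, y

    def test_exact_counts(self):
        X, Z, y = self._population()
        s = rp.draw_case_control(X, Z, y, 500, 700, seed=1)
        assert int(s.y.sum()) == 500
        assert int((1 - s.y).sum()) == 700

    def test_shortfall_error_names_the_numbers(self):
        X, Z, y = self._population(n=100)
        with pytest.raises(rp.GenerationError, match="short by"):
            rp.draw_case_control(X, Z, y, 10_000, 10, seed=1)

    def test_seed_contract(self):
        X, Z, y = self._population()
        s1 = rp.draw_case_control(X, Z, y, 300, 300, seed=5)
        s2 = rp.draw_case_control(X, Z, y, 300, 300, seed=5)
        s3 = rp.draw_case_control(X, Z, y, 300, 300, seed=6)
        assert np.array_equal(s1.X, s2.X)
        assert not np.array_equal(s1.X, s3.X)
        assert int(s3.y.sum()) == 300


class TestReplicates:
    def test_replicates_reproducible_and_distinct(self):
        pop = rp.PopulationConfig(n_pop=5000)
        a = rp.simulate_replicate(pop=pop, n_cases=300, n_controls=300, seed=1)
        b = rp.simulate_replicate(pop=pop, n_cases=300, n_controls=300, seed=1)
        c = rp.simulate_replicate(pop=pop, n_cases=300, n_controls=300, seed=2)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)
        assert not np.array_equal(a.X, c.X)
        assert a.gamma == b.gamma

    def test_estimator_facing_view_excludes_confounders(self):
        pop = rp.PopulationConfig(n_pop=4000)
        s = rp.simulate_replicate(pop=pop, n_cases=200, n_controls=200, seed=0)
        X, y = s.observed()
        assert X.shape[1] == 50
        assert "y" in s.to_frame().columns
        assert not any(c.startswith("z") for c in s.to_frame().columns)

    def test_cohort_roundtrip(self, tmp_path):
        pop = rp.PopulationConfig(n_pop=4000)
        s = rp.simulate_replicate(pop=pop, n_cases=150, n_controls=150, seed=8)
        rp.write_cohort(s, tmp_path / "c.csv")
        s2 = rp.read_cohort(tmp_path / "c.csv")
        assert np.array_equal(s.X, s2.X)
        assert np.array_equal(s.y, s2.y)
        assert s2.Z is None
        assert s2.gamma == pytest.approx(s.gamma)
        assert np.allclose(s2.truth.prevalences, s.truth.prevalences)
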