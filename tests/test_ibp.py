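import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from scipy.stats import multivariate_normal

from endofactor.ibp import (IBPConfig, IBPPosterior, PropertyAssignments,
                            collapsed_loglik, fit_ibp, gibbs_conditional_prob,
                            harmonic_number, ibp_log_pmf,
                            posterior_mean_loadings, sample_alpha,
                            sample_ibp_prior, select_assignment)
from endofactor.synthetic import SyntheticConfig, generate_cohort


def _matrix_normal_oracle(Z, X, sx, sa):
    """Exact marginal: columns of X are i.i.d. N(0, sa^2 Z Z' + sx^2 I)."""
    N = X.shape[0]
    cov = sa**2 * Z @ Z.T + sx**2 * np.eye(N)
    return sum(multivariate_normal.logpdf(X[:, d], mean=np.zeros(N), cov=cov)
               for d in range(X.shape[1]))


class TestCollapsedLoglik:
    @pytest.mark.parametrize("n,d,k,seed", [(4, 3, 2, 0), (6, 5, 3, 1),
                                            (3, 2, 1, 2), (8, 4, 4, 3)])
    def test_matches_exact_matrix_normal_marginal(self, n, d, k, seed):
        rng = np.random.default_rng(seed)
        Z = (rng.random((n, k)) < 0.5).astype(float)
        X = rng.normal(size=(n, d))
        for sx, sa in [(0.7, 1.3), (1.0, 0.5)]:
            assert collapsed_loglik(Z, X, sx, sa) == pytest.approx(
                _matrix_normal_oracle(Z, X, sx, sa), abs=1e-8)

    def test_k_zero_closed_form(self, rng):
        X = rng.normal(size=(5, 4))
        sx = 0.8
        expected = float(np.sum(-0.5 * np.log(2 * np.pi * sx**2)
                                - X**2 / (2 * sx**2)))
        assert collapsed_loglik(np.zeros((5, 0)), X, sx, 1.0) == pytest.approx(
            expected, abs=1e-10)

    def test_column_permutation_invariance(self, rng):
        Z = (rng.random((6, 3)) < 0.5).astype(float)
        X = rng.normal(size=(6, 4))
        base = collapsed_loglik(Z, X, 0.6, 1.1)
        assert collapsed_loglik(Z[:, [2, 0, 1]], X, 0.6, 1.1) == base

    def test_row_permutation_invariance(self, rng):
        Z = (rng.random((7, 2)) < 0.5).astype(float)
        X = rng.normal(size=(7, 3))
        perm = rng.permutation(7)
        assert collapsed_loglik(Z[perm], X[perm], 0.5, 1.0) == pytest.approx(
            collapsed_loglik(Z, X, 0.5, 1.0), abs=1e-9)
        assert ibp_log_pmf(Z[perm], 1.5) == pytest.approx(
            ibp_log_pmf(Z, 1.5), abs=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            collapsed_loglik(np.ones((3, 1)), rng.normal(size=(4, 2)), 1, 1)


def _exchangeable_pmf_log(Z, alpha):
    """Independent implementation of the IBP equivalence-class pmf."""
    N, K = Z.shape
    if K == 0:
        return -alpha * harmonic_number(N)
    m = Z.sum(axis=0)
    cols = {}
    for k in range(K):
        cols[tuple(Z[:, k])] = cols.get(tuple(Z[:, k]), 0) + 1
    log_kh = sum(float(gammaln(c + 1)) for c in cols.values())
    total = K * np.log(alpha) - alpha * harmonic_number(N) - log_kh
    for mk in m:
        total += float(gammaln(N - mk + 1) + gammaln(mk) - gammaln(N + 1))
    return total


class TestGibbsConditional:
    def test_matches_enumeration_of_prior_times_likelihood(self, rng):
        """On a 3-subject instance the conditional P(z_ik=1|rest) must equal
        the renormalized product of the exchangeable pmf and the collapsed
        likelihood over the two values of z_ik."""
        X = rng.normal(size=(3, 2))
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        sx, sa, alpha = 0.7, 1.2, 1.0
        for (i, k) in [(0, 0), (1, 1), (2, 0), (2, 1), (0, 1), (1, 0)]:
            Z1, Z0 = Z.copy(), Z.copy()
            Z1[i, k], Z0[i, k] = 1.0, 0.0
            m_other = Z[:, k].sum() - Z[i, k]
            if m_other <= 0 or m_other >= 3:
                continue
            w1 = (_exchangeable_pmf_log(Z1, alpha)
                  + collapsed_loglik(Z1, X, sx, sa))
            w0 = (_exchangeable_pmf_log(Z0, alpha)
                  + collapsed_loglik(Z0, X, sx, sa))
            expected = 1.0 / (1.0 + np.exp(w0 - w1))
            got = gibbs_conditional_prob(Z, X, i, k, sx, sa)
            assert got == pytest.approx(expected, abs=1e-6)


class TestAlphaAndPrior:
    def test_harmonic_number_value(self):
        assert harmonic_number(10) == pytest.approx(2.9289682539682538, abs=1e-12)

    def test_alpha_posterior_mean_small_case(self):
        draws = [sample_alpha(0, 1, (1.0, 1.0), s) for s in range(100_000)]
        # Gamma(1, 2): mean 0.5
        assert np.mean(draws) == pytest.approx(0.50, abs=0.01)

    def test_alpha_posterior_mean_general(self):
        rng = np.random.default_rng(0)
        draws = [sample_alpha(7, 50, (2.0, 3.0), rng) for _ in range(100_000)]
        expected = (2 + 7) / (3 + harmonic_number(50))
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected) < 3 * se

    def test_prior_predictive_feature_count(self):
        rng = np.random.default_rng(1)
        ks = [sample_ibp_prior(2.0, 10, rng).shape[1] for _ in range(2000)]
        expected = 2.0 * harmonic_number(10)
        se = np.std(ks, ddof=1) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - expected) < 3 * se


class TestPosteriorMeanLoadings:
    def test_identity_z_small_ratio_limit(self, rng):
        X = rng.normal(size=(4, 6))
        A = posterior_mean_loadings(np.eye(4), X, sigma_x=1e-6, sigma_a=1.0)
        np.testing.assert_allclose(A, X, atol=1e-6)

    def test_matches_sklearn_ridge(self, rng):
        from sklearn.linear_model import Ridge
        Z = (rng.random((20, 3)) < 0.5).astype(float)
        Z[0] = 1.0      # ensure no empty column
        X = rng.normal(size=(20, 5))
        sx, sa = 0.7, 1.3
        A = posterior_mean_loadings(Z, X, sx, sa)
        ridge = Ridge(alpha=(sx / sa) ** 2, fit_intercept=False).fit(Z, X)
        np.testing.assert_allclose(A, ridge.coef_.T, atol=1e-8)

    def test_all_ones_column_closed_form(self, rng):
        X = rng.normal(size=(10, 4))
        A = posterior_mean_loadings(np.ones((10, 1)), X, 0.5, 1.0)
        np.testing.assert_allclose(A[0], X.sum(axis=0) / (10 + 0.25), atol=1e-12)

    def test_empty_column_raises(self, rng):
        Z = np.zeros((5, 1))
        with pytest.raises(ValueError, match="zero"):
            posterior_mean_loadings(Z, rng.normal(size=(5, 2)), 1, 1)


class TestSelectAssignment:
    def _posterior(self, samples, logpost):
        n = samples[0].shape[0]
        return IBPPosterior(z_samples=samples,
                            sample_logpost=np.asarray(logpost, float),
                            alpha_trace=np.zeros(1),
                            joint_logpost_trace=np.zeros(1),
                            K_trace=np.zeros(1, int),
                            selected_Z=np.zeros((n, 0), np.int8),
                            A_mean=np.zeros((0, 1)),
                            sigma_x=1.0, sigma_a=1.0)

    def test_picks_maximum_log_posterior_sample(self):
        samples = [np.array([[1, 0], [0, 1]], np.int8),
                   np.array([[1, 1], [0, 1]], np.int8),
                   np.array([[0, 1], [1, 1]], np.int8)]
        out = select_assignment(self._posterior(samples, [-5.0, -3.0, -9.0]))
        assert np.array_equal(np.sort(out.Z.sum(axis=0)), [1, 2])

    def test_left_orders_and_prunes(self):
        Z = np.array([[0, 1, 0], [1, 0, 0]], np.int8)   # one empty column
        out = select_assignment(self._posterior([Z], [0.0]))
        assert np.array_equal(out.Z, np.array([[1, 0], [0, 1]]))

    def test_no_empty_columns_over_fuzzed_posteriors(self, rng):
        for _ in range(30):
            n, k = rng.integers(2, 6), rng.integers(1, 5)
            samples = [(rng.random((n, k)) < 0.4).astype(np.int8)
                       for _ in range(3)]
            out = select_assignment(self._posterior(samples,
                                                    rng.normal(size=3)))
            if out.Z.shape[1]:
                assert (out.Z.sum(axis=0) > 0).all()

    def test_empty_posterior_raises(self):
        post = self._posterior([np.zeros((2, 1), np.int8)], [0.0])
        post.z_samples = []
        post.sample_logpost = np.array([])
        with pytest.raises(ValueError):
            select_assignment(post)


class TestFitIBP:
    def test_noise_free_recovery(self):
        """Spec-style recovery: 3 well-separated planted features, no noise."""
        cfg = SyntheticConfig(n_subjects=100, n_edges=20, n_properties_true=3,
                              n_factors_true=3, mean_active_properties=1.2,
                              dirichlet_concentration=0.5, noise_scale=0.0,
                              site_effect_scale=0.0, seed=4)
        cohort = generate_cohort(cfg)
        post = fit_ibp(cohort.X, IBPConfig(n_sweeps=150, burn_in=75, seed=1))
        Zt = cohort.ground_truth.Z_true
        K = post.selected_Z.shape[1]
        assert 3 <= K <= 5
        cost = np.array([[np.abs(post.selected_Z[:, a].astype(float)
                                 - Zt[:, b]).mean()
                          for b in range(3)] for a in range(K)])
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].mean() <= 0.02

    def test_all_zero_input_gives_no_features(self):
        post = fit_ibp(np.zeros((20, 5)),
                       IBPConfig(n_sweeps=40, burn_in=20, seed=0,
                                 sigma_x=1.0, sigma_a=1.0))
        assert post.selected_Z.shape[1] == 0

    def test_determinism_bit_for_bit(self, rng):
        X = rng.normal(size=(25, 8))
        cfg = IBPConfig(n_sweeps=50, burn_in=25, seed=9)
        p1, p2 = fit_ibp(X, cfg), fit_ibp(X, cfg)
        np.testing.assert_array_equal(p1.K_trace, p2.K_trace)
        np.testing.assert_array_equal(p1.alpha_trace, p2.alpha_trace)
        np.testing.assert_array_equal(p1.joint_logpost_trace,
                                      p2.joint_logpost_trace)
        np.testing.assert_array_equal(p1.selected_Z, p2.selected_Z)

    def test_selected_z_is_left_ordered_and_nonempty_columns(self, rng):
        X = rng.normal(size=(30, 6)) + 2.0
        post = fit_ibp(X, IBPConfig(n_sweeps=60, burn_in=30, seed=2))
        Z = post.selected_Z
        if Z.shape[1] > 1:
            readings = [tuple(c) for c in Z.T]
            assert readings == sorted(readings, reverse=True)
        if Z.shape[1]:
            assert (Z.sum(axis=0) > 0).all()

    def test_non_finite_input_raises(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_ibp(X, IBPConfig(n_sweeps=10, burn_in=5))

    def test_property_assignment_validation(self):
        with pytest.raises(ValueError, match="binary"):
            PropertyAssignments(np.array([[0.5]]), ("p0",))
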