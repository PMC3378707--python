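"""Truncated multivariate-normal moments against closed forms and sampling."""

import numpy as np
import pytest
from scipy.stats import norm

from censmix import conditional_then_truncate, mvn_cdf, truncated_mvn_moments
from censmix.tmvn import TruncationMassError, bvn_cdf

from oracles import rejection_truncated_moments


def random_pd_cov(rng, d, nonneg=False):
    A = rng.normal(size=(d, d))
    C = A @ A.T + d * np.eye(d) * 0.1
    if nonneg:
        C = np.abs(C)
        C = C + d * np.eye(d)
    return C


class TestMvnCdf:
    def test_univariate_median(self):
        assert mvn_cdf([0.0], [0.0], [[1.0]]) == pytest.approx(0.5, abs=1e-12)

    def test_bivariate_independent_product(self):
        val = mvn_cdf([0.0, 0.0], [0.0, 0.0], np.eye(2))
        assert val == pytest.approx(0.25, abs=1e-10)

    def test_bivariate_orthant_closed_form(self):
        # P(X<=0, Y<=0) = 1/4 + arcsin(rho)/(2 pi) = 1/3 at rho = 1/2
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        val = mvn_cdf([0.0, 0.0], [0.0, 0.0], cov)
        assert val == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_trivariate_orthant_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            C = random_pd_cov(rng, 3)
            s = np.sqrt(np.diag(C))
            R = C / np.outer(s, s)
            exact = 0.125 + (
                np.arcsin(R[0, 1]) + np.arcsin(R[0, 2]) + np.arcsin(R[1, 2])
            ) / (4 * np.pi)
            assert mvn_cdf(np.zeros(3), np.zeros(3), C) == pytest.approx(
                exact, abs=5e-6
            )

    def test_reproducible_higher_dimension(self):
        rng = np.random.default_rng(5)
        C = random_pd_cov(rng, 5)
        u = rng.normal(size=5)
        vals = {mvn_cdf(u, np.zeros(5), C) for _ in range(3)}
        assert len(vals) == 1

    def test_unbounded_coordinates_marginalised(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        val = mvn_cdf([0.0, np.inf], [0.0, 0.0], cov)
        assert val == pytest.approx(0.5, abs=1e-12)

    def test_non_pd_cov_raises_with_diagnostics(self):
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            mvn_cdf([0.0, 0.0], [0.0, 0.0], np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_bvn_matches_scipy_grid(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(0)
        for _ in range(100):
            h, k = rng.normal(0, 2, 2)
            rho = rng.uniform(-0.999, 0.999)
            ref = multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]]
            )
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=5e-7)


class TestTruncatedMoments:
    def test_univariate_standard_halfline(self):
        tm = truncated_mvn_moments([0.0], [0.0], [[1.0]])
        assert tm.mean[0] == pytest.approx(-np.sqrt(2 / np.pi), abs=1e-10)
        assert tm.mean[0] == pytest.approx(-0.7979, abs=1e-4)
        assert tm.cov[0, 0] == pytest.approx(1 - 2 / np.pi, abs=1e-10)
        assert tm.cov[0, 0] == pytest.approx(0.3634, abs=1e-4)
        assert tm.log_mass == pytest.approx(np.log(0.5), abs=1e-12)

    def test_all_unbounded_is_identity(self):
        mean = np.array([1.0, 2.0])
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        tm = truncated_mvn_moments([np.inf, np.inf], mean, cov)
        np.testing.assert_allclose(tm.mean, mean)
        np.testing.assert_allclose(tm.cov, cov)
        assert tm.log_mass == 0.0

    def test_bivariate_against_rejection_sampling(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        tm = truncated_mvn_moments([0.0, 0.0], [0.0, 0.0], cov)
        rng = np.random.default_rng(42)
        m, C, mass, kept = rejection_truncated_moments(
            [0.0, 0.0], cov, [0.0, 0.0], 10**6, rng
        )
        se = 1.0 / np.sqrt(kept)
        np.testing.assert_allclose(tm.mean, m, atol=3 * se)
        np.testing.assert_allclose(tm.cov, C, atol=3 * se)
        assert np.exp(tm.log_mass) == pytest.approx(mass, abs=3 * se)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_random_cases_against_rejection_sampling(self, d):
        rng = np.random.default_rng(100 + d)
        for _ in range(5):
            cov = random_pd_cov(rng, d)
            mean = rng.normal(0, 1, d)
            upper = mean + rng.uniform(-0.5, 1.5, d) * np.sqrt(np.diag(cov))
            tm = truncated_mvn_moments(upper, mean, cov)
            m, C, _, kept = rejection_truncated_moments(
                mean, cov, upper, 400_000, rng
            )
            scale = np.sqrt(np.diag(cov).max())
            se = 3 * scale / np.sqrt(kept)
            np.testing.assert_allclose(tm.mean, m, atol=3 * se)
            np.testing.assert_allclose(np.atleast_2d(tm.cov), np.atleast_2d(C),
                                       atol=3 * scale**2 / np.sqrt(kept) * 3)

    def test_log_mass_consistent_with_cdf(self):
        rng = np.random.default_rng(8)
        for d in (1, 2, 3):
            cov = random_pd_cov(rng, d)
            mean = rng.normal(size=d)
            upper = mean + rng.uniform(-0.5, 1.0, d)
            tm = truncated_mvn_moments(upper, mean, cov)
            assert tm.log_mass == pytest.approx(
                np.log(mvn_cdf(upper, mean, cov)), abs=1e-10
            )

    def test_truncated_mean_below_mean_nonneg_correlations(self):
        rng = np.random.default_rng(9)
        for d in (2, 3):
            for _ in range(5):
                cov = random_pd_cov(rng, d, nonneg=True)
                mean = rng.normal(size=d)
                upper = mean + rng.uniform(0.0, 1.0, d)
                tm = truncated_mvn_moments(upper, mean, cov)
                assert np.all(tm.mean <= mean + 1e-10)

    def test_univariate_variance_reduction(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            v = rng.uniform(0.2, 3.0)
            u = rng.normal(0, 2)
            tm = truncated_mvn_moments([u], [0.0], [[v]])
            assert tm.cov[0, 0] <= v + 1e-12

    def test_moment_continuity_in_limits(self):
        cov = np.array([[1.0, 0.4], [0.4, 1.0]])
        u = np.array([0.3, -0.2])
        tm1 = truncated_mvn_moments(u, np.zeros(2), cov)
        tm2 = truncated_mvn_moments(u + 1e-6, np.zeros(2), cov)
        assert np.max(np.abs(tm1.mean - tm2.mean)) < 1e-4
        assert np.max(np.abs(tm1.cov - tm2.cov)) < 1e-4

    def test_psd_of_truncated_covariance(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            cov = random_pd_cov(rng, 3)
            mean = rng.normal(size=3)
            upper = mean + rng.uniform(-1, 1, 3)
            tm = truncated_mvn_moments(upper, mean, cov)
            assert np.linalg.eigvalsh(tm.cov)[0] >= -1e-8
            assert tm.log_mass <= 0.0

    def test_mass_floor_raises(self):
        with pytest.raises(TruncationMassError):
            truncated_mvn_moments([-40.0], [0.0], [[1.0]])


class TestConditionalThenTruncate:
    def test_zero_cross_covariance_reduces_to_marginal(self):
        cov = np.diag([1.0, 2.0, 3.0])
        cov[1, 2] = cov[2, 1] = 0.8
        mean = np.array([0.5, -0.3, 0.2])
        tm = conditional_then_truncate(
            q_obs=[1.2], limits=[0.0, 0.0], mean=mean, cov=cov,
            obs_idx=[0], cens_idx=[1, 2],
        )
        ref = truncated_mvn_moments(
            [0.0, 0.0], mean[1:], cov[1:, 1:]
        )
        np.testing.assert_allclose(tm.mean, ref.mean, atol=1e-12)
        np.testing.assert_allclose(tm.cov, ref.cov, atol=1e-12)

    def test_single_censored_is_univariate_formula(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        mean = np.array([0.0, 1.0])
        q_obs, limit = 0.5, 0.8
        tm = conditional_then_truncate(
            [q_obs], [limit], mean, cov, obs_idx=[0], cens_idx=[1]
        )
        cm = mean[1] + cov[1, 0] / cov[0, 0] * (q_obs - mean[0])
        cv = cov[1, 1] - cov[1, 0] ** 2 / cov[0, 0]
        a = (limit - cm) / np.sqrt(cv)
        lam = norm.pdf(a) / norm.cdf(a)
        assert tm.mean[0] == pytest.approx(cm - np.sqrt(cv) * lam, abs=1e-10)
        assert tm.cov[0, 0] == pytest.approx(cv * (1 - a * lam - lam**2), abs=1e-10)

    def test_against_conditional_rejection_oracle(self):
        rng = np.random.default_rng(21)
        cov = random_pd_cov(rng, 3)
        mean = np.array([0.2, -0.1, 0.4])
        q_obs = np.array([mean[0] + 0.3])
        limits = mean[1:] + np.array([0.5, 0.2])
        tm = conditional_then_truncate(
            q_obs, limits, mean, cov, obs_idx=[0], cens_idx=[1, 2]
        )
        # exact conditional, then reject above the limits
        Voo = cov[0, 0]
        cmean = mean[1:] + cov[1:, 0] * (q_obs[0] - mean[0]) / Voo
        ccov = cov[1:, 1:] - np.outer(cov[1:, 0], cov[0, 1:]) / Voo
        m, C, _, kept = rejection_truncated_moments(
            cmean, ccov, limits, 10**6, rng
        )
        se = 3 * np.sqrt(np.diag(ccov).max() / kept)
        np.testing.assert_allclose(tm.mean, m, atol=3 * se)
        np.testing.assert_allclose(tm.cov, C, atol=9 * se)

    def test_empty_censored_rejected(self):
        with pytest.raises(ValueError):
            conditional_then_truncate(
                [0.0, 1.0], [], np.zeros(2), np.eye(2),
                obs_idx=[0, 1], cens_idx=[],
            )

    def test_singular_observed_block_raises(self):
        cov = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            conditional_then_truncate(
                [0.0, 0.0], [0.0], np.zeros(3), cov,
                obs_idx=[0, 1], cens_idx=[2],
            )
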