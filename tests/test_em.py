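"""E-step moments, M-step closed forms, EM ascent and reductions."""

import numpy as np
import pytest

from censmix import (
    Dataset,
    EMControl,
    IndividualData,
    ModelSpec,
    Parameters,
    e_step,
    fit,
    initialize,
    m_step,
    observed_loglik,
)
from censmix.em import expected_complete_loglik

from conftest import make_mixture_data
from oracles import mixture_of_regressions_em


def simple_lmm_data(seed=0, N=40, n=5, censor_at=None):
    rng = np.random.default_rng(seed)
    inds = []
    for i in range(N):
        t = np.sort(rng.uniform(0, 1, n))
        X = np.column_stack([np.ones(n), t])
        b = rng.normal(0, 0.7)
        y = X @ [1.0, -2.0] + b + rng.normal(0, 0.5, n)
        if censor_at is None:
            c, q = np.zeros(n, int), y
        else:
            c = (y <= censor_at).astype(int)
            q = np.where(c == 1, censor_at, y)
        inds.append(IndividualData(id=i, q=q, c=c, X=X, Z=np.ones((n, 1)), times=t))
    return Dataset(inds)


class TestEStep:
    def test_single_component_no_censoring_blup(self):
        data = simple_lmm_data(seed=1, N=10)
        params = Parameters(pi=[1.0], alpha=[[1.0, -2.0]], sigma2=[0.25],
                            Psi=[[[0.5]]])
        es = e_step(data, params)
        np.testing.assert_allclose(es.tau, 1.0)
        for i, ind in enumerate(data):
            np.testing.assert_allclose(es.yhat(i, 0), ind.q, atol=1e-12)
            np.testing.assert_allclose(es.Omega(i, 0), 0.0, atol=1e-12)
            V = 0.25 * np.eye(ind.n) + 0.5
            blup = 0.5 * np.ones((1, ind.n)) @ np.linalg.solve(
                V, ind.q - ind.X @ [1.0, -2.0]
            )
            np.testing.assert_allclose(es.bhat(i, 0), blup, atol=1e-10)

    def test_identical_components_posterior_equals_prior(self):
        data = simple_lmm_data(seed=2, N=8)
        params = Parameters(
            pi=[0.3, 0.7], alpha=[[1.0, -2.0], [1.0, -2.0]],
            sigma2=[0.25, 0.25], Psi=np.repeat([[[0.5]]], 2, axis=0),
        )
        es = e_step(data, params)
        np.testing.assert_allclose(es.tau, np.broadcast_to([0.3, 0.7], (8, 2)),
                                   atol=1e-12)

    def test_tau_rows_sum_to_one(self, censored_mixture_data):
        data, _ = censored_mixture_data
        params = initialize(data, ModelSpec(G=2), np.random.default_rng(0))
        es = e_step(data, params)
        np.testing.assert_allclose(es.tau.sum(axis=1), 1.0, atol=1e-10)

    def test_omega_observed_block_zero_and_bcov_psd(self, censored_mixture_data):
        data, _ = censored_mixture_data
        params = initialize(data, ModelSpec(G=2), np.random.default_rng(0))
        es = e_step(data, params)
        ind = next(i for i in range(data.N) if data[i].c.sum() > 0)
        Om = es.Omega(ind, 0)
        obs = np.where(data[ind].c == 0)[0]
        assert np.all(Om[obs, :] == 0.0) and np.all(Om[:, obs] == 0.0)
        B = es.Bcov(ind, 0)
        assert np.linalg.eigvalsh(B)[0] >= -1e-10

    def test_censored_moments_match_joint_rejection_oracle(self):
        # one individual, n=2, first coordinate observed, second censored
        q_obs, limit = 0.6, -0.2
        X = np.ones((2, 1))
        Z = np.ones((2, 1))
        ind = IndividualData(id=0, q=[q_obs, limit], c=[0, 1], X=X, Z=Z)
        data = Dataset([ind])
        params = Parameters(pi=[1.0], alpha=[[0.4]], sigma2=[0.3], Psi=[[[0.6]]])
        es = e_step(data, params)

        rng = np.random.default_rng(99)
        n_draw = 4 * 10**6
        beta = rng.normal(0, np.sqrt(0.6), n_draw)
        y1 = 0.4 + beta + rng.normal(0, np.sqrt(0.3), n_draw)
        y2 = 0.4 + beta + rng.normal(0, np.sqrt(0.3), n_draw)
        h = 0.02
        keep = (np.abs(y1 - q_obs) < h) & (y2 <= limit)
        kept = keep.sum()
        assert kept > 3000
        se = 1.0 / np.sqrt(kept)
        assert es.yhat(0, 0)[1] == pytest.approx(y2[keep].mean(), abs=3 * se)
        assert es.Omega(0, 0)[1, 1] == pytest.approx(y2[keep].var(), abs=3 * se)
        assert es.bhat(0, 0)[0] == pytest.approx(beta[keep].mean(), abs=3 * se)
        assert es.Bcov(0, 0)[0, 0] == pytest.approx(beta[keep].var(), abs=3 * se)
        # cross-covariance between the censored response and the random effect
        cross = np.cov(y2[keep], beta[keep])[0, 1]
        assert es.YBcross(0, 0)[1, 0] == pytest.approx(cross, abs=3 * se)

    def test_starvation_signal(self):
        data = simple_lmm_data(seed=3, N=10)
        params = Parameters(
            pi=[1 - 1e-12, 1e-12], alpha=[[1.0, -2.0], [500.0, 0.0]],
            sigma2=[0.25, 0.25], Psi=np.repeat([[[0.5]]], 2, axis=0),
        )
        from censmix.em import ComponentStarvationError

        with pytest.raises(ComponentStarvationError):
            e_step(data, params, starvation_floor=1e-6)


class TestMStep:
    def test_hard_assignment_reduces_to_groupwise_ols(self):
        rng = np.random.default_rng(4)
        inds = []
        for i in range(20):
            n = 4
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            inds.append(IndividualData(id=i, q=y, c=np.zeros(n), X=X))
        data = Dataset(inds)
        spec = ModelSpec(G=2, random_intercept=False)
        assign = rng.integers(0, 2, 20)
        params0 = Parameters(
            pi=[0.5, 0.5], alpha=np.zeros((2, 2)), sigma2=[1.0, 1.0]
        )
        es = e_step(data, params0)
        es.tau[:] = 0.0
        es.tau[np.arange(20), assign] = 1.0
        out = m_step(data, es, spec)
        for g in range(2):
            Xg = np.vstack([data[i].X for i in range(20) if assign[i] == g])
            yg = np.concatenate([data[i].q for i in range(20) if assign[i] == g])
            beta, *_ = np.linalg.lstsq(Xg, yg, rcond=None)
            np.testing.assert_allclose(out.alpha[g], beta, atol=1e-10)
            resid = yg - Xg @ beta
            np.testing.assert_allclose(
                out.sigma2[g], np.mean(resid**2), atol=1e-12
            )
            assert out.pi[g] == pytest.approx(np.mean(assign == g))

    def test_equal_residual_pooling_identity(self):
        # two identical components sharing the data 50/50 pool to the G=1 value
        data = simple_lmm_data(seed=5, N=15)
        p1 = Parameters(pi=[1.0], alpha=[[1.0, -2.0]], sigma2=[0.3], Psi=[[[0.4]]])
        es1 = e_step(data, p1)
        out1 = m_step(data, es1, ModelSpec(G=1))
        p2 = Parameters(
            pi=[0.5, 0.5], alpha=[[1.0, -2.0]] * 2, sigma2=[0.3, 0.3],
            Psi=np.repeat([[[0.4]]], 2, axis=0),
        )
        es2 = e_step(data, p2)
        out2 = m_step(
            data, es2,
            ModelSpec(G=2, equal_residual_variance=True, equal_random_variance=True),
        )
        assert out2.sigma2[0] == pytest.approx(out1.sigma2[0], abs=1e-12)
        assert out2.sigma2[1] == out2.sigma2[0]
        np.testing.assert_allclose(out2.Psi[0], out1.Psi[0], atol=1e-12)

    def test_update_locally_maximises_q_function(self):
        data, _ = make_mixture_data(N=25, seed=8)
        spec = ModelSpec(G=2)
        params = initialize(data, spec, np.random.default_rng(1))
        es = e_step(data, params)
        new = m_step(data, es, spec)
        q_star = expected_complete_loglik(data, es, new, spec)
        rng = np.random.default_rng(2)
        for _ in range(100):
            pert = new.copy()
            block = rng.integers(0, 4)
            if block == 0:
                d = rng.normal(0, 1e-3, 2)
                d -= d.mean()
                pert.pi = np.abs(pert.pi + d)
                pert.pi /= pert.pi.sum()
            elif block == 1:
                pert.alpha = pert.alpha + rng.normal(0, 1e-3, pert.alpha.shape)
            elif block == 2:
                pert.sigma2 = pert.sigma2 * np.exp(rng.normal(0, 1e-3, 2))
            else:
                pert.Psi = pert.Psi * np.exp(rng.normal(0, 1e-3, (2, 1, 1)))
            assert expected_complete_loglik(data, es, pert, spec) <= q_star + 1e-10


class TestAscentAndFit:
    def test_em_cycle_never_decreases_loglik(self):
        data, _ = make_mixture_data(N=30, seed=9)
        spec = ModelSpec(G=2)
        rng = np.random.default_rng(3)
        params = initialize(data, spec, rng)
        for _ in range(10):
            ll_before = observed_loglik(data, params)
            es = e_step(data, params)
            params = m_step(data, es, spec)
            ll_after = observed_loglik(data, params)
            assert ll_after >= ll_before - 1e-8

    def test_trace_non_decreasing(self, censored_mixture_data, fast_control):
        data, _ = censored_mixture_data
        res = fit(data, ModelSpec(G=2), fast_control)
        assert np.all(np.diff(res.trace) >= -1e-8)

    def test_reduction_to_mixed_model(self):
        import statsmodels.api as sm

        data = simple_lmm_data(seed=11, N=50)
        res = fit(data, ModelSpec(G=1), EMControl(tol=1e-10, max_iter=5000, seed=0))
        endog = np.concatenate([ind.q for ind in data])
        exog = np.vstack([ind.X for ind in data])
        groups = np.concatenate([[i] * ind.n for i, ind in enumerate(data)])
        ref = sm.MixedLM(endog, exog, groups).fit(reml=False)
        assert res.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_reduction_to_mixture_of_regressions(self):
        data, assign = make_mixture_data(
            N=40, seed=12, random_intercept=False, limit=None, psi=0.0
        )
        rng = np.random.default_rng(5)
        init_assign = rng.integers(0, 2, data.N)
        tau0 = np.zeros((data.N, 2))
        tau0[np.arange(data.N), init_assign] = 1.0
        spec = ModelSpec(G=2, random_intercept=False)
        res = fit(data, spec, EMControl(tol=1e-10, max_iter=3000, seed=0),
                  init_tau=tau0)
        X_list = [ind.X for ind in data]
        y_list = [ind.q for ind in data]
        ll_ref, *_ = mixture_of_regressions_em(
            X_list, y_list, 2, init_assign, tol=1e-10
        )
        assert res.loglik == pytest.approx(ll_ref, abs=1e-6)

    def test_self_consistency_at_convergence(self, censored_mixture_data):
        data, _ = censored_mixture_data
        res = fit(data, ModelSpec(G=2),
                  EMControl(tol=1e-10, max_iter=3000, n_starts=2, seed=7))
        es = e_step(data, res.params)
        new = m_step(data, es, ModelSpec(G=2))
        for name in ("pi", "alpha", "sigma2"):
            a, b = getattr(res.params, name), getattr(new, name)
            assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-3)) < 1e-4
        assert np.max(np.abs(res.params.Psi - new.Psi)) < 1e-4

    def test_permutation_equivariance(self, censored_mixture_data):
        data, _ = censored_mixture_data
        spec = ModelSpec(G=2)
        params = initialize(data, spec, np.random.default_rng(4))
        es = e_step(data, params)
        out = m_step(data, es, spec)
        es_p = e_step(data, params.permuted([1, 0]))
        out_p = m_step(data, es_p, spec)
        assert es_p.loglik == pytest.approx(es.loglik, abs=1e-9)
        np.testing.assert_allclose(es_p.tau, es.tau[:, [1, 0]], atol=1e-10)
        np.testing.assert_allclose(out_p.alpha, out.alpha[[1, 0]], atol=1e-8)

    def test_censoring_aware_fit_recovers_low_tail(self):
        # naive limit-as-observed fitting biases the low end upward
        data, assign = make_mixture_data(N=80, seed=13)
        spec = ModelSpec(G=2)
        ctl = EMControl(tol=1e-6, max_iter=400, n_starts=2, seed=1)
        res = fit(data, spec, ctl)
        naive_inds = [
            IndividualData(id=ind.id, q=ind.q, c=np.zeros(ind.n, int),
                           X=ind.X, Z=ind.Z, times=ind.times)
            for ind in data
        ]
        naive = fit(Dataset(naive_inds, spline=data.spline), spec, ctl)
        from censmix import match_components

        true_alpha = np.array([[4.5, -4.0, -3.5], [4.3, -4.1, -1.0]])
        truth = Parameters(pi=[0.55, 0.45], alpha=true_alpha,
                           sigma2=[0.3, 0.3], Psi=np.repeat([[[0.16]]], 2, 0))
        low = true_alpha[0]  # component crossing the limit
        X_end = data[0].X[-1]  # latest time point, deepest censoring
        perm_a = match_components(res.params, truth)
        perm_n = match_components(naive.params, truth)
        err_aware = abs(X_end @ res.params.alpha[perm_a[0]] - X_end @ low)
        err_naive = abs(X_end @ naive.params.alpha[perm_n[0]] - X_end @ low)
        assert err_naive > err_aware


class TestInitialize:
    def test_single_component_deterministic(self):
        data = simple_lmm_data(seed=14, N=12)
        a = initialize(data, ModelSpec(G=1), np.random.default_rng(0))
        b = initialize(data, ModelSpec(G=1), np.random.default_rng(99))
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)

    def test_seed_reproducibility(self, censored_mixture_data):
        data, _ = censored_mixture_data
        a = initialize(data, ModelSpec(G=3), np.random.default_rng(5))
        b = initialize(data, ModelSpec(G=3), np.random.default_rng(5))
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_partitions_never_empty_over_many_seeds(self):
        data = simple_lmm_data(seed=15, N=30)
        spec = ModelSpec(G=3)
        for s in range(300):
            params = initialize(data, spec, np.random.default_rng(s))
            assert np.all(params.pi >= 2 / 30 - 1e-12)

    def test_censored_values_start_at_limits(self):
        # with all responses censored the initial alpha reproduces the limits
        n = 3
        inds = [
            IndividualData(id=i, q=np.full(n, 2.0), c=np.ones(n, int),
                           X=np.ones((n, 1)), Z=np.ones((n, 1)))
            for i in range(4)
        ]
        data = Dataset(inds)
        params = initialize(data, ModelSpec(G=1), np.random.default_rng(0))
        assert params.alpha[0, 0] == pytest.approx(2.0)
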