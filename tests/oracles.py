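"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — rejection sampling, direct
summation, textbook recursions — and shares no code with the implementation
under test.
"""

from __future__ import annotations

import numpy as np


def rejection_truncated_moments(mean, cov, upper, n_draws, rng):
    """Monte-Carlo moments of X | X <= upper by rejection sampling.

    Returns (mean, cov, mass, n_kept); standard errors scale as
    1/sqrt(n_kept).
    """
    X = rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float),
                                size=n_draws)
    keep = X[np.all(X <= np.asarray(upper, float), axis=1)]
    if len(keep) < 10:
        raise RuntimeError("too few accepted draws for a usable oracle")
    return keep.mean(axis=0), np.cov(keep.T), len(keep) / n_draws, len(keep)


def naive_mixture_loglik(data, params):
    """Direct sum-of-products mixture likelihood (no log-sum-exp)."""
    from scipy.stats import multivariate_normal

    total = 0.0
    for ind in data:
        mix = 0.0
        for g in range(params.G):
            mu = ind.X @ params.alpha[g]
            V = params.sigma2[g] * np.eye(ind.n)
            if ind.Z is not None and params.Psi is not None:
                V = V + ind.Z @ params.Psi[g] @ ind.Z.T
            mix += params.pi[g] * multivariate_normal.pdf(ind.q, mu, V)
        total += np.log(mix)
    return total


def de_boor_basis(times, knots, degree):
    """B-spline basis by the textbook de Boor recursion (all functions)."""
    times = np.asarray(times, float)
    knots = np.asarray(knots, float)
    n_basis = len(knots) - degree - 1
    B = np.zeros((len(times), len(knots) - 1))
    # degree 0
    for j in range(len(knots) - 1):
        left, right = knots[j], knots[j + 1]
        # the interval ending at the right boundary is closed on the right
        closed = (right == knots[-1]) and (left < right)
        B[:, j] = np.where(
            (times >= left) & ((times < right) | (closed & (times <= right))),
            1.0, 0.0,
        )
    for d in range(1, degree + 1):
        Bn = np.zeros((len(times), len(knots) - d - 1))
        for j in range(len(knots) - d - 1):
            den1 = knots[j + d] - knots[j]
            den2 = knots[j + d + 1] - knots[j + 1]
            term = np.zeros(len(times))
            if den1 > 0:
                term = term + (times - knots[j]) / den1 * B[:, j]
            if den2 > 0:
                term = term + (knots[j + d + 1] - times) / den2 * B[:, j + 1]
            Bn[:, j] = term
        B = Bn
    return B[:, :n_basis]


def pair_counting_ari(a, b):
    """Adjusted Rand index straight from the pair-counting definition."""
    from math import comb

    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    ulab_a, ulab_b = np.unique(a), np.unique(b)
    nij = np.array(
        [[np.sum((a == x) & (b == y)) for y in ulab_b] for x in ulab_a]
    )
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in ai)
    sum_b = sum(comb(int(v), 2) for v in bj)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def mixture_of_regressions_em(X_list, y_list, G, init_assign, tol=1e-10,
                              max_iter=2000):
    """Textbook EM for a mixture of linear regressions on grouped data.

    Each individual contributes a block (X_i, y_i); component membership is
    shared within the block, errors are iid N(0, sigma2_g).  Starts from the
    given hard assignment.  Returns (loglik, pi, beta, sigma2).
    """
    from scipy.stats import norm

    N = len(X_list)
    p = X_list[0].shape[1]
    tau = np.zeros((N, G))
    tau[np.arange(N), init_assign] = 1.0
    pi = np.full(G, 1.0 / G)
    beta = np.zeros((G, p))
    sigma2 = np.ones(G)
    ll_old = -np.inf
    for _ in range(max_iter):
        # M-step
        pi = tau.mean(axis=0)
        for g in range(G):
            XtX = sum(tau[i, g] * X_list[i].T @ X_list[i] for i in range(N))
            Xty = sum(tau[i, g] * X_list[i].T @ y_list[i] for i in range(N))
            beta[g] = np.linalg.solve(XtX + 1e-10 * np.eye(p), Xty)
            num = sum(
                tau[i, g] * np.sum((y_list[i] - X_list[i] @ beta[g]) ** 2)
                for i in range(N)
            )
            den = sum(tau[i, g] * len(y_list[i]) for i in range(N))
            sigma2[g] = max(num / den, 1e-12)
        # E-step
        logL = np.zeros((N, G))
        for g in range(G):
            for i in range(N):
                logL[i, g] = np.sum(
                    norm.logpdf(y_list[i], X_list[i] @ beta[g],
                                np.sqrt(sigma2[g]))
                )
        logw = logL + np.log(np.maximum(pi, 1e-300))
        mx = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - mx)
        ll = float(np.sum(mx.ravel() + np.log(w.sum(axis=1))))
        tau = w / w.sum(axis=1, keepdims=True)
        if abs(ll - ll_old) / max(abs(ll_old), 1e-300) < tol:
            break
        ll_old = ll
    return ll, pi, beta, sigma2
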