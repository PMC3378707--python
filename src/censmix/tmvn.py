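"""Moments of multivariate normal distributions truncated from above.

Left-censored Gaussian responses are, conditionally on the observed
coordinates, distributed as a multivariate normal restricted to the
lower-open rectangle ``{x : x <= u}``.  The E-step of the EM algorithm needs
the probability mass of that rectangle together with the first and second
moments of the restricted distribution.  Both are available in closed form
in terms of normal CDFs of dimension ``d``, ``d-1`` and ``d-2`` (the
classical Tallis-type formulas): writing ``alpha(u) = P(X <= u)`` for
``X ~ N(mu, S)``,

    E[X | X <= u]   = mu - S F / alpha,
    Cov[X | X <= u] = S + S (H / alpha - F F' / alpha^2) S,

where ``F = d alpha / d u`` (each entry a univariate density times a
``(d-1)``-dimensional CDF) and ``H`` is the Hessian of ``alpha`` in ``u``
(off-diagonal entries a bivariate density times a ``(d-2)``-dimensional CDF).

CDF backends: exact univariate (``scipy.special.ndtr``), a vectorised
Gauss-Legendre bivariate rule, a trivariate reduction to the bivariate via an
equal-probability-transform quadrature, and, for d >= 4, scipy's Genz
quasi-Monte-Carlo CDF with a fixed-seed generator so results are reproducible.

Unbounded coordinates (no truncation) are encoded with ``numpy.inf``; they
are marginalised out before any CDF call, so no infinite value ever enters
the quadratures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

__all__ = [
    "TruncatedMoments",
    "TruncationMassError",
    "mvn_cdf",
    "bvn_cdf",
    "truncated_mvn_moments",
    "conditional_then_truncate",
]

logger = logging.getLogger(__name__)

#: probability mass below which the truncation region is declared degenerate
MASS_FLOOR = 1e-12

#: floor applied to probabilities before taking logarithms
LOG_FLOOR = 1e-300

_SQRT_2PI = np.sqrt(2.0 * np.pi)


class TruncationMassError(ValueError):
    """Raised when the truncation rectangle carries (numerically) no mass."""


@dataclass(frozen=True)
class TruncatedMoments:
    """First two moments of ``X | X <= u`` plus the log mass of the region."""

    mean: np.ndarray
    cov: np.ndarray
    log_mass: float


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(x)) / _SQRT_2PI


def _phi2(x, y, rho):
    """Standard bivariate normal density, vectorised."""
    omr2 = np.maximum(1.0 - rho * rho, 1e-15)
    z = (x * x - 2.0 * rho * x * y + y * y) / omr2
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(omr2))


# ---------------------------------------------------------------------------
# CDF backends
# ---------------------------------------------------------------------------

_GL48 = leggauss(48)
_GL64 = leggauss(64)


def _gl_nodes(rule, lo, hi):
    """Affine map of Gauss-Legendre nodes/weights onto [lo, hi] (vectorised)."""
    x, w = rule
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    return mid[..., None] + half[..., None] * x, half[..., None] * w


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorised over broadcastable ``h``, ``k``, ``rho``.  Moderate
    correlations use the sin-substitution single integral

        Phi2 = Phi(h) Phi(k)
               + (1/2pi) int_0^{asin rho} exp(-(h^2+k^2-2hk sin t)/(2cos^2 t)) dt

    with a 48-point Gauss-Legendre rule; |rho| > 0.925 switches to an
    equal-probability-transform quadrature of the conditional representation,
    split at the sigmoid centre for accuracy.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, float)
    rho = np.clip(rho, -1.0, 1.0)

    near = np.abs(rho) >= 0.99999
    mid = (~near) & (np.abs(rho) <= 0.925)
    high = ~(near | mid)

    if np.any(near):
        hp, kp, rp = h[near], k[near], rho[near]
        pos = np.minimum(ndtr(hp), ndtr(kp))
        neg = np.maximum(ndtr(hp) + ndtr(kp) - 1.0, 0.0)
        out[near] = np.where(rp > 0, pos, neg)

    if np.any(mid):
        hm, km, rm = h[mid], k[mid], rho[mid]
        theta, w = _gl_nodes(_GL48, np.zeros_like(rm), np.arcsin(rm))
        st = np.sin(theta)
        ct2 = np.maximum(1.0 - st * st, 1e-300)
        expo = -(hm[..., None] ** 2 + km[..., None] ** 2
                 - 2.0 * hm[..., None] * km[..., None] * st) / (2.0 * ct2)
        integral = np.sum(w * np.exp(expo), axis=-1) / (2.0 * np.pi)
        out[mid] = ndtr(hm) * ndtr(km) + integral

    if np.any(high):
        hh, kh, rh = h[high], k[high], rho[high]
        s = np.sqrt(np.maximum(1.0 - rh * rh, 1e-300))
        ph = ndtr(hh)
        # the inner factor Phi((k - rho z)/s) is a sigmoid in z centred at
        # z* = k/rho with width ~ s/|rho|; place quadrature panels so the
        # transition region is always resolved
        zstar = kh / rh
        width = s / np.abs(rh)
        edges = np.stack(
            [
                np.zeros_like(ph),
                ndtr(zstar - 6.0 * width),
                ndtr(zstar),
                ndtr(zstar + 6.0 * width),
                ph,
            ],
            axis=-1,
        )
        edges = np.clip(edges, 0.0, ph[..., None])
        edges = np.maximum.accumulate(edges, axis=-1)
        total = np.zeros_like(hh)
        for j in range(edges.shape[-1] - 1):
            lo, hi = edges[..., j], edges[..., j + 1]
            p, w = _gl_nodes(_GL64, lo, hi)
            z = ndtri(np.clip(p, 1e-320, 1 - 1e-16))
            inner = ndtr((kh[..., None] - rh[..., None] * z) / s[..., None])
            total += np.sum(w * inner, axis=-1)
        out[high] = total

    return np.clip(out, 0.0, 1.0)


def _tvn_cdf_batch(b: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """P(Z <= b_i) rows of ``b`` (m, 3) under N(0, corr); shared correlation.

    Conditions on the first coordinate and integrates the conditional
    bivariate CDF with a 64-point rule after the equal-probability transform
    z = ndtri(p * t), which concentrates nodes where the outer coordinate
    carries mass.
    """
    r01, r02, r12 = corr[0, 1], corr[0, 2], corr[1, 2]
    s1 = np.sqrt(max(1.0 - r01 * r01, 1e-15))
    s2 = np.sqrt(max(1.0 - r02 * r02, 1e-15))
    rc = np.clip((r12 - r01 * r02) / (s1 * s2), -1.0, 1.0)

    p0 = ndtr(b[:, 0])
    t, w = _gl_nodes(_GL64, np.zeros_like(p0), p0)
    z = ndtri(np.clip(t, 1e-320, 1 - 1e-16))
    inner = bvn_cdf(
        (b[:, 1, None] - r01 * z) / s1, (b[:, 2, None] - r02 * z) / s2, rc
    )
    return np.clip(np.sum(w * inner, axis=-1), 0.0, 1.0)


def _cdf_std(b: np.ndarray, corr: np.ndarray, seed: int = 1234) -> float:
    """Standardised MVN CDF dispatching on dimension (b finite, 1-D)."""
    d = b.shape[0]
    if d == 0:
        return 1.0
    if d == 1:
        return float(ndtr(b[0]))
    if d == 2:
        return float(bvn_cdf(b[0], b[1], corr[0, 1]))
    if d == 3:
        return float(_tvn_cdf_batch(b[None, :], corr)[0])
    rng = np.random.default_rng(seed)
    return float(
        multivariate_normal.cdf(
            b, mean=np.zeros(d), cov=corr,
            maxpts=200_000 * d, abseps=1e-9, releps=1e-9, rng=rng,
        )
    )


def _standardise(upper, mean, cov):
    upper = np.atleast_1d(np.asarray(upper, float))
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ValueError("covariance has non-positive diagonal")
    corr = cov / np.outer(sd, sd)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    a = (upper - mean) / sd
    return a, corr, sd


def _check_pd(cov: np.ndarray) -> None:
    w = np.linalg.eigvalsh(np.atleast_2d(cov))
    if w[0] <= 0:
        cond = np.inf if w[0] <= 0 else w[-1] / w[0]
        raise np.linalg.LinAlgError(
            f"covariance not positive definite: min eigenvalue {w[0]:.3e}, "
            f"max {w[-1]:.3e}, condition number {cond:.3e}"
        )


def mvn_cdf(upper, mean, cov, *, seed: int = 1234) -> float:
    """P(X <= upper componentwise) for X ~ N(mean, cov).

    ``numpy.inf`` entries of ``upper`` mark unconstrained coordinates and are
    marginalised out.  Deterministic for d <= 3; for larger d a Genz
    quasi-Monte-Carlo evaluation with a fixed-seed generator is used, so
    repeated calls agree to at least six significant digits.
    """
    a, corr, _ = _standardise(upper, mean, cov)
    if not np.all(np.isfinite(np.asarray(mean, float))):
        raise ValueError("non-finite mean")
    _check_pd(cov)
    bounded = np.isfinite(a)
    if not np.any(bounded):
        return 1.0
    idx = np.where(bounded)[0]
    return _cdf_std(a[idx], corr[np.ix_(idx, idx)], seed=seed)


# ---------------------------------------------------------------------------
# Truncated moments, batched over rows of limits (shared covariance)
# ---------------------------------------------------------------------------


def _F_vector(a: np.ndarray, corr: np.ndarray, seed: int) -> np.ndarray:
    """Gradient of the CDF in the upper limits: rows of ``a`` (m, d)."""
    m, d = a.shape
    if d == 1:
        return _phi(a)
    F = np.empty((m, d))
    for k in range(d):
        others = [j for j in range(d) if j != k]
        r = corr[others, k]
        s = np.sqrt(np.maximum(1.0 - r * r, 1e-15))
        c = (a[:, others] - np.outer(a[:, k], r)) / s  # (m, d-1)
        if d == 2:
            tail = ndtr(c[:, 0])
        else:
            sub = corr[np.ix_(others, others)] - np.outer(r, r)
            sub = sub / np.outer(s, s)
            np.fill_diagonal(sub, 1.0)
            if d == 3:
                tail = bvn_cdf(c[:, 0], c[:, 1], sub[0, 1])
            else:
                tail = np.array([_cdf_std(c[i], sub, seed) for i in range(m)])
        F[:, k] = _phi(a[:, k]) * tail
    return F


def _F_pairs(a: np.ndarray, corr: np.ndarray, seed: int) -> np.ndarray:
    """Off-diagonal CDF Hessian entries F_kq, shape (m, d, d), zero diagonal."""
    m, d = a.shape
    out = np.zeros((m, d, d))
    for k in range(d):
        for q in range(k + 1, d):
            r = corr[k, q]
            dens = _phi2(a[:, k], a[:, q], r)
            others = [j for j in range(d) if j not in (k, q)]
            if not others:
                tail = 1.0
            else:
                R2 = corr[np.ix_([k, q], [k, q])]
                R2inv = np.linalg.inv(R2)
                B = corr[np.ix_(others, [k, q])] @ R2inv  # (d-2, 2)
                cm = a[:, [k, q]] @ B.T  # conditional means (m, d-2)
                cv = corr[np.ix_(others, others)] - B @ corr[np.ix_([k, q], others)]
                cs = np.sqrt(np.maximum(np.diag(cv), 1e-15))
                c = (a[:, others] - cm) / cs
                if len(others) == 1:
                    tail = ndtr(c[:, 0])
                else:
                    sub = cv / np.outer(cs, cs)
                    np.fill_diagonal(sub, 1.0)
                    if len(others) == 2:
                        tail = bvn_cdf(c[:, 0], c[:, 1], sub[0, 1])
                    else:
                        tail = np.array(
                            [_cdf_std(c[i], sub, seed) for i in range(m)]
                        )
            out[:, k, q] = out[:, q, k] = dens * tail
    return out


def _cdf_batch(a: np.ndarray, corr: np.ndarray, seed: int) -> np.ndarray:
    m, d = a.shape
    if d == 1:
        return ndtr(a[:, 0])
    if d == 2:
        return bvn_cdf(a[:, 0], a[:, 1], corr[0, 1])
    if d == 3:
        return _tvn_cdf_batch(a, corr)
    return np.array([_cdf_std(a[i], corr, seed) for i in range(m)])


def truncated_moments_batch(a: np.ndarray, corr: np.ndarray, *, seed: int = 1234):
    """Moments of Z | Z <= a_i for standardised Z ~ N(0, corr).

    Parameters
    ----------
    a : (m, d) array of standardised upper limits (finite).
    corr : (d, d) correlation matrix shared across rows.

    Returns
    -------
    mean : (m, d), cov : (m, d, d), alpha : (m,) region probabilities.
    Rows with ``alpha`` below :data:`MASS_FLOOR` get moments imputed at the
    limit (mean = a, cov = 0); callers inspect ``alpha`` to detect them.
    """
    a = np.atleast_2d(np.asarray(a, float))
    m, d = a.shape
    alpha = _cdf_batch(a, corr, seed)
    ok = alpha > MASS_FLOOR
    alpha_safe = np.where(ok, alpha, 1.0)

    F = _F_vector(a, corr, seed)  # (m, d)
    P = _F_pairs(a, corr, seed)  # (m, d, d) off-diagonal
    # Hessian diagonal: H_kk = -a_k F_k - sum_{q != k} r_kq F_kq
    H = P.copy()
    diag = -a * F - np.einsum("kq,mkq->mk", corr, P)
    H[:, np.arange(d), np.arange(d)] = diag

    mean = -(F @ corr.T) / alpha_safe[:, None]
    M = H / alpha_safe[:, None, None] - np.einsum(
        "mk,mq->mkq", F, F
    ) / (alpha_safe ** 2)[:, None, None]
    cov = corr[None] + np.einsum("kl,mlj,ji->mki", corr, M, corr)
    cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))

    if not np.all(ok):
        mean[~ok] = a[~ok]
        cov[~ok] = 0.0
    return mean, cov, alpha


def truncated_mvn_moments(upper, mean, cov, *, seed: int = 1234) -> TruncatedMoments:
    """Mean, covariance and log mass of ``X | X <= upper``, X ~ N(mean, cov).

    Coordinates with ``upper = numpy.inf`` are unconstrained; with every
    coordinate unconstrained the input moments are returned with log mass 0.
    Raises :class:`TruncationMassError` when the region mass falls below
    :data:`MASS_FLOOR`.
    """
    a, corr, sd = _standardise(upper, mean, cov)
    _check_pd(cov)
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    d = a.shape[0]
    bounded = np.where(np.isfinite(a))[0]
    if bounded.size == 0:
        return TruncatedMoments(mean.copy(), cov.copy(), 0.0)

    free = np.setdiff1d(np.arange(d), bounded)
    aB = a[bounded][None, :]
    corrB = corr[np.ix_(bounded, bounded)]
    mB, cB, alpha = truncated_moments_batch(aB, corrB, seed=seed)
    if alpha[0] <= MASS_FLOOR:
        raise TruncationMassError(
            f"truncation region mass {alpha[0]:.3e} below floor {MASS_FLOOR:.0e}"
        )
    # back to the original scale on the bounded block
    sdB = sd[bounded]
    muB = mean[bounded] + sdB * mB[0]
    covB = (cB[0] * np.outer(sdB, sdB))

    out_mean = mean.copy()
    out_cov = cov.copy()
    out_mean[bounded] = muB
    out_cov[np.ix_(bounded, bounded)] = covB
    if free.size:
        # unconstrained coordinates respond to the truncated block through
        # the usual Gaussian regression coefficients
        SBB = cov[np.ix_(bounded, bounded)]
        SFB = cov[np.ix_(free, bounded)]
        G = SFB @ np.linalg.inv(SBB)  # (|free|, |bounded|)
        out_mean[free] = mean[free] + G @ (muB - mean[bounded])
        SFF = cov[np.ix_(free, free)]
        out_cov[np.ix_(free, free)] = SFF - G @ SFB.T + G @ covB @ G.T
        cross = G @ covB
        out_cov[np.ix_(free, bounded)] = cross
        out_cov[np.ix_(bounded, free)] = cross.T
    log_mass = float(np.log(max(alpha[0], LOG_FLOOR)))
    return TruncatedMoments(out_mean, 0.5 * (out_cov + out_cov.T), log_mass)


def conditional_then_truncate(
    q_obs, limits, mean, cov, obs_idx, cens_idx, *, seed: int = 1234
) -> TruncatedMoments:
    """Condition a joint normal on observed coordinates, then truncate.

    Returns the moments of the censored block ``X_C`` given ``X_O = q_obs``
    and ``X_C <= limits``; ``log_mass`` is the log conditional probability of
    the censored rectangle.
    """
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    obs_idx = np.asarray(obs_idx, int)
    cens_idx = np.asarray(cens_idx, int)
    if cens_idx.size == 0:
        raise ValueError("cens_idx must be nonempty")
    d = mean.shape[0]
    if sorted(obs_idx.tolist() + cens_idx.tolist()) != list(range(d)):
        raise ValueError("obs_idx and cens_idx must partition the coordinates")
    q_obs = np.atleast_1d(np.asarray(q_obs, float))
    limits = np.atleast_1d(np.asarray(limits, float))

    if obs_idx.size == 0:
        return truncated_mvn_moments(limits, mean[cens_idx],
                                     cov[np.ix_(cens_idx, cens_idx)], seed=seed)
    Voo = cov[np.ix_(obs_idx, obs_idx)]
    Vco = cov[np.ix_(cens_idx, obs_idx)]
    try:
        sol = np.linalg.solve(Voo, (q_obs - mean[obs_idx]))
        A = np.linalg.solve(Voo, Vco.T).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "observed-block covariance is singular"
        ) from err
    cmean = mean[cens_idx] + Vco @ sol
    ccov = cov[np.ix_(cens_idx, cens_idx)] - A @ Vco.T
    ccov = 0.5 * (ccov + ccov.T)
    return truncated_mvn_moments(limits, cmean, ccov, seed=seed)
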