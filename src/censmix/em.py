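"""EM algorithm for finite mixtures of censored linear mixed models.

Three kinds of missing data are integrated out in the E-step: the component
membership of each individual, the random effects, and the latent values of
the left-censored responses.  Posterior component probabilities follow from
the observed-data component likelihoods; the censored responses' conditional
moments come from the truncated-multivariate-normal closed forms in
:mod:`censmix.tmvn`; the random-effects moments follow by Gaussian
regression of beta_i on Y_i:

    bhat    = Psi Z' V^-1 (yhat - mu)
    Bcov    = Psi - Psi Z' V^-1 Z Psi + Psi Z' V^-1 Omega V^-1 Z Psi
    YBcross = Omega V^-1 Z Psi

with V = Z Psi Z' + sigma2 I the marginal covariance and Omega the
conditional covariance of Y (nonzero only on the censored block).  The
M-step is in closed form; the residual variance uses the full second-moment
correction  E||e||^2 = ||yhat - X a - Z bhat||^2 + tr(Omega)
+ tr(Z Bcov Z') - 2 tr(YBcross Z'),  evaluated at the updated alpha.

For speed, individuals are grouped by (design matrices, censoring pattern):
within a group all expensive matrix factorisations are shared and the
truncated-moment computations are vectorised across individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from scipy.special import log_ndtr

from . import tmvn
from .core import Dataset, ModelSpec, Parameters

__all__ = [
    "EMControl",
    "EStepResult",
    "FitResult",
    "ComponentStarvationError",
    "e_step",
    "m_step",
    "initialize",
    "fit",
    "expected_complete_loglik",
]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


class ComponentStarvationError(RuntimeError):
    """A component's total responsibility fell below the floor."""


class AllChainsFailedError(RuntimeError):
    """Every EM chain aborted; carries per-chain diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        super().__init__(f"all EM chains failed: {diagnostics}")


@dataclass
class EMControl:
    """Tuning constants of the EM driver."""

    tol: float = 1e-6
    max_iter: int = 2000
    n_starts: int = 5
    seed: int | None = None
    starvation_floor: float = 1e-6

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class _Group:
    """Individuals sharing design matrices and censoring pattern."""

    idx: np.ndarray  # indices into the dataset
    X: np.ndarray  # (n, p)
    Z: np.ndarray | None  # (n, r)
    cmask: np.ndarray  # (n,) bool, True = censored
    Q: np.ndarray  # (m, n) recorded responses (limits where censored)

    @property
    def m(self) -> int:
        return self.Q.shape[0]

    @property
    def n(self) -> int:
        return self.Q.shape[1]

    @property
    def obs(self) -> np.ndarray:
        return np.where(~self.cmask)[0]

    @property
    def cen(self) -> np.ndarray:
        return np.where(self.cmask)[0]


def make_groups(data: Dataset) -> list:
    """Group individuals by identical (X, Z, censoring pattern)."""
    table: dict = {}
    for i, ind in enumerate(data):
        if ind.X is None:
            raise ValueError(f"individual {ind.id}: no design matrix attached")
        zkey = b"" if ind.Z is None else np.ascontiguousarray(ind.Z).tobytes()
        key = (
            np.ascontiguousarray(ind.X).tobytes(),
            zkey,
            np.ascontiguousarray(ind.c).tobytes(),
        )
        table.setdefault(key, []).append(i)
    groups = []
    for key, idx in table.items():
        first = data[idx[0]]
        groups.append(
            _Group(
                idx=np.asarray(idx, int),
                X=first.X,
                Z=first.Z,
                cmask=first.c.astype(bool),
                Q=np.vstack([data[i].q for i in idx]),
            )
        )
    return groups


@dataclass
class _GroupMoments:
    """Per-(group, component) conditional moments of (Y, beta)."""

    loglik: np.ndarray  # (m,)
    yhat: np.ndarray  # (m, n)
    Omega_c: np.ndarray  # (m, nc, nc) censored block of Cov(Y | obs)
    bhat: np.ndarray | None  # (m, r)
    Bcov: np.ndarray | None  # (m, r, r)
    YB_c: np.ndarray | None  # (m, nc, r) censored rows of Cov(Y, beta)
    tr_Omega: np.ndarray  # (m,)
    tr_ZBZ: np.ndarray  # (m,)
    tr_YBZ: np.ndarray  # (m,)
    mu: np.ndarray  # (n,)


@dataclass
class EStepResult:
    """Posterior weights and conditional moments from one E-step.

    ``tau`` is the N x G responsibility matrix; the per-individual
    conditional moments are stored grouped for efficiency and exposed
    through the accessor methods.
    """

    tau: np.ndarray
    loglik: float
    loglik_i: np.ndarray  # (N,) observed-data log-likelihood per individual
    logL: np.ndarray  # (N, G) per-component log-likelihoods
    groups: list = field(repr=False)
    moments: list = field(repr=False)  # moments[g][j] -> _GroupMoments
    _pos: dict = field(repr=False, default=None)

    def __post_init__(self):
        if self._pos is None:
            self._pos = {}
            for j, grp in enumerate(self.groups):
                for pos, i in enumerate(grp.idx):
                    self._pos[int(i)] = (j, pos)

    def _locate(self, i):
        return self._pos[int(i)]

    def yhat(self, i: int, g: int) -> np.ndarray:
        j, pos = self._locate(i)
        return self.moments[g][j].yhat[pos]

    def Omega(self, i: int, g: int) -> np.ndarray:
        j, pos = self._locate(i)
        grp, mom = self.groups[j], self.moments[g][j]
        out = np.zeros((grp.n, grp.n))
        cen = grp.cen
        if cen.size:
            out[np.ix_(cen, cen)] = mom.Omega_c[pos]
        return out

    def bhat(self, i: int, g: int) -> np.ndarray | None:
        j, pos = self._locate(i)
        mom = self.moments[g][j]
        return None if mom.bhat is None else mom.bhat[pos]

    def Bcov(self, i: int, g: int) -> np.ndarray | None:
        j, pos = self._locate(i)
        mom = self.moments[g][j]
        return None if mom.Bcov is None else mom.Bcov[pos]

    def YBcross(self, i: int, g: int) -> np.ndarray | None:
        j, pos = self._locate(i)
        grp, mom = self.groups[j], self.moments[g][j]
        if mom.YB_c is None:
            return None
        out = np.zeros((grp.n, grp.Z.shape[1]))
        if grp.cen.size:
            out[grp.cen] = mom.YB_c[pos]
        return out


_GH_Z, _GH_W = np.polynomial.hermite_e.hermegauss(80)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)  # weights of the standard normal factor


def _trunc_indep_std(a: np.ndarray):
    """Univariate truncated-normal moments, columns independent.

    ``a`` holds standardised upper limits; returns (zmean, zvar, log_mass)
    with the inverse Mills ratio evaluated through ``log_ndtr`` so deep
    tails stay finite.
    """
    logPhi = log_ndtr(a)
    log_mass = logPhi.sum(axis=-1)
    lam = np.exp(-0.5 * a * a - 0.5 * _LOG_2PI - logPhi)
    zmean = -lam
    zvar = np.maximum(1.0 - a * lam - lam * lam, 0.0)
    return zmean, zvar, log_mass


def _trunc_factor1(U: np.ndarray, cmean: np.ndarray, load: np.ndarray,
                   sigma: float):
    """Truncated moments when Cov = sigma^2 I + load load' (one factor).

    Conditionally on the latent factor w ~ N(0,1) the coordinates are
    independent truncated normals, so the rectangle mass and moments reduce
    to one-dimensional integrals over w, evaluated with an 80-point
    Gauss-Hermite rule.

    Parameters: ``U`` and ``cmean`` are (m, nc) limits and conditional
    means, ``load`` the (nc,) factor loadings.  Returns (mean, cov, mass).
    """
    w, wt = _GH_Z, _GH_W
    mu = cmean[:, :, None] + load[None, :, None] * w[None, None, :]
    a = (U[:, :, None] - mu) / sigma
    logPhi = log_ndtr(a)
    p = np.exp(logPhi.sum(axis=1))  # (m, K)
    mass = p @ wt
    lam = np.exp(-0.5 * a * a - 0.5 * _LOG_2PI - logPhi)
    t1 = mu - sigma * lam  # E[X_j | w, truncated]
    v1 = (sigma * sigma) * np.maximum(1.0 - a * lam - lam * lam, 0.0)
    ok = mass > tmvn.MASS_FLOOR
    mass_safe = np.where(ok, mass, 1.0)
    pw = p * wt[None, :]
    mean = np.einsum("mjk,mk->mj", t1, pw) / mass_safe[:, None]
    sec = np.einsum("mjk,mlk,mk->mjl", t1, t1, pw)
    nc = U.shape[1]
    diag = np.arange(nc)
    sec[:, diag, diag] += np.einsum("mjk,mk->mj", v1, pw)
    sec /= mass_safe[:, None, None]
    cov = sec - mean[:, :, None] * mean[:, None, :]
    cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
    if not np.all(ok):
        mean[~ok] = U[~ok]
        cov[~ok] = 0.0
    return mean, cov, mass


def _component_moments(grp: _Group, alpha_g, sigma2_g, Psi_g) -> _GroupMoments:
    """Conditional moments of (Y, beta) for every individual in a group."""
    n, m = grp.n, grp.m
    mu = grp.X @ alpha_g
    V = sigma2_g * np.eye(n)
    if grp.Z is not None and Psi_g is not None:
        V = V + grp.Z @ Psi_g @ grp.Z.T
    cf = cho_factor(V, lower=True)
    obs, cen = grp.obs, grp.cen
    nc = cen.size

    loglik = np.zeros(m)
    yhat = grp.Q.copy()
    Omega_c = np.zeros((m, nc, nc))

    if nc == 0:
        dev = grp.Q - mu
        sol = cho_solve(cf, dev.T)  # (n, m)
        maha = np.einsum("nm,nm->m", dev.T, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        loglik = -0.5 * (n * _LOG_2PI + logdet + maha)
    else:
        r = 0 if grp.Z is None or Psi_g is None else grp.Z.shape[1]
        if obs.size:
            Voo = V[np.ix_(obs, obs)]
            cfo = cho_factor(Voo, lower=True)
            dev_o = grp.Q[:, obs] - mu[obs]  # (m, no)
            sol_o = cho_solve(cfo, dev_o.T)  # (no, m)
            maha = np.einsum("nm,nm->m", dev_o.T, sol_o)
            logdet_o = 2.0 * np.sum(np.log(np.diag(cfo[0])))
            loglik += -0.5 * (obs.size * _LOG_2PI + logdet_o + maha)
            Vco = V[np.ix_(cen, obs)]
            Acoef = cho_solve(cfo, Vco.T).T  # (nc, no)
            cmean = mu[cen] + dev_o @ Acoef.T  # (m, nc)
            S = V[np.ix_(cen, cen)] - Acoef @ Vco.T
        else:
            cmean = np.broadcast_to(mu[cen], (m, nc)).copy()
            S = V[np.ix_(cen, cen)].copy()
        S = 0.5 * (S + S.T)
        U = grp.Q[:, cen]

        if r == 0:
            # no random effects: censored coordinates are conditionally
            # independent with residual variance sigma2
            sd0 = np.sqrt(sigma2_g)
            zmean, zvar, logm = _trunc_indep_std((U - cmean) / sd0)
            loglik += logm
            yhat[:, cen] = cmean + sd0 * zmean
            Omega_c = np.zeros((m, nc, nc))
            Omega_c[:, np.arange(nc), np.arange(nc)] = sd0 * sd0 * zvar
        elif r == 1 and nc >= 2:
            # diagonal-plus-rank-one conditional covariance: exact reduction
            # to univariate truncated moments given the latent factor
            if obs.size:
                ZPo = grp.Z[obs] @ Psi_g  # (no, r)
                Psi_t = Psi_g - ZPo.T @ cho_solve(cfo, ZPo)
            else:
                Psi_t = Psi_g
            load = grp.Z[cen, 0] * np.sqrt(max(float(Psi_t[0, 0]), 0.0))
            ymean, Omega_c, mass = _trunc_factor1(
                U, cmean, load, float(np.sqrt(sigma2_g))
            )
            n_under = int(np.sum(mass <= tmvn.MASS_FLOOR))
            if n_under:
                logger.warning(
                    "%d individual(s): censored-region mass below floor; "
                    "imputing censored values at their limits", n_under,
                )
            loglik += np.log(np.maximum(mass, tmvn.LOG_FLOOR))
            yhat[:, cen] = ymean
        else:
            sd = np.sqrt(np.diag(S))
            corr = S / np.outer(sd, sd)
            np.fill_diagonal(corr, 1.0)
            a = (U - cmean) / sd
            zmean, zcov, mass = tmvn.truncated_moments_batch(a, corr)
            n_under = int(np.sum(mass <= tmvn.MASS_FLOOR))
            if n_under:
                logger.warning(
                    "%d individual(s): censored-region mass below floor; "
                    "imputing censored values at their limits", n_under,
                )
            loglik += np.log(np.maximum(mass, tmvn.LOG_FLOOR))
            yhat[:, cen] = cmean + zmean * sd
            Omega_c = zcov * np.outer(sd, sd)[None]

    tr_Omega = np.einsum("mcc->m", Omega_c) if nc else np.zeros(m)

    if grp.Z is None or Psi_g is None:
        return _GroupMoments(
            loglik=loglik, yhat=yhat, Omega_c=Omega_c, bhat=None, Bcov=None,
            YB_c=None, tr_Omega=tr_Omega, tr_ZBZ=np.zeros(m),
            tr_YBZ=np.zeros(m), mu=mu,
        )

    ZP = grp.Z @ Psi_g  # (n, r)
    M = cho_solve(cf, ZP)  # V^-1 Z Psi, (n, r)
    bhat = (yhat - mu) @ M  # (m, r)
    C0 = Psi_g - ZP.T @ M  # Psi - Psi Z' V^-1 Z Psi
    if nc:
        Mc = M[cen]  # (nc, r)
        Bcov = C0[None] + np.einsum("cr,mcd,ds->mrs", Mc, Omega_c, Mc)
        YB_c = np.einsum("mcd,dr->mcr", Omega_c, Mc)
        tr_YBZ = np.einsum("mcr,cr->m", YB_c, grp.Z[cen])
    else:
        Bcov = np.broadcast_to(C0, (m,) + C0.shape).copy()
        YB_c = np.zeros((m, 0, ZP.shape[1]))
        tr_YBZ = np.zeros(m)
    ZtZ = grp.Z.T @ grp.Z
    tr_ZBZ = np.einsum("mrs,sr->m", Bcov, ZtZ)
    return _GroupMoments(
        loglik=loglik, yhat=yhat, Omega_c=Omega_c, bhat=bhat, Bcov=Bcov,
        YB_c=YB_c, tr_Omega=tr_Omega, tr_ZBZ=tr_ZBZ, tr_YBZ=tr_YBZ, mu=mu,
    )


def e_step(
    data: Dataset,
    params: Parameters,
    *,
    groups: list | None = None,
    starvation_floor: float = 0.0,
) -> EStepResult:
    """Posterior component weights and conditional moments of (Y, beta)."""
    if groups is None:
        groups = make_groups(data)
    G, N = params.G, data.N
    logL = np.zeros((N, G))
    moments = []
    for g in range(G):
        Psi_g = None if params.Psi is None else params.Psi[g]
        row = []
        for grp in groups:
            mom = _component_moments(grp, params.alpha[g], params.sigma2[g], Psi_g)
            logL[grp.idx, g] = mom.loglik
            row.append(mom)
        moments.append(row)
    logw = logL + np.log(params.pi)[None, :]
    lse = logsumexp(logw, axis=1)
    tau = np.exp(logw - lse[:, None])
    if starvation_floor > 0:
        tot = tau.sum(axis=0)
        if np.any(tot < starvation_floor * N):
            g_bad = int(np.argmin(tot))
            raise ComponentStarvationError(
                f"component {g_bad} responsibility {tot[g_bad]:.3e} below "
                f"floor {starvation_floor * N:.3e}"
            )
    return EStepResult(
        tau=tau, loglik=float(lse.sum()), loglik_i=lse, logL=logL,
        groups=groups, moments=moments,
    )


def _repair_psd(P: np.ndarray, label: str) -> np.ndarray:
    w, U = np.linalg.eigh(0.5 * (P + P.T))
    if w[0] < 0:
        logger.warning("%s not PSD (min eig %.3e); clipping at 0", label, w[0])
        w = np.maximum(w, 0.0)
        P = (U * w) @ U.T
    return 0.5 * (P + P.T)


def m_step(data: Dataset, es: EStepResult, spec: ModelSpec) -> Parameters:
    """Closed-form parameter update maximising the expected complete log-lik."""
    G = es.tau.shape[1]
    N = data.N
    has_rand = es.moments[0][0].bhat is not None
    r = es.moments[0][0].bhat.shape[1] if has_rand else 0
    p = es.groups[0].X.shape[1]

    S_tau = es.tau.sum(axis=0)
    pi = S_tau / N

    alpha = np.zeros((G, p))
    Psi = np.zeros((G, r, r)) if has_rand else None
    for g in range(G):
        gram = np.zeros((p, p))
        rhs = np.zeros(p)
        for j, grp in enumerate(es.groups):
            t = es.tau[grp.idx, g]
            mom = es.moments[g][j]
            resid0 = mom.yhat
            if has_rand:
                resid0 = resid0 - mom.bhat @ grp.Z.T
            gram += t.sum() * (grp.X.T @ grp.X)
            rhs += grp.X.T @ (t[:, None] * resid0).sum(axis=0)
        try:
            alpha[g] = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError as err:
            rank = np.linalg.matrix_rank(gram)
            raise np.linalg.LinAlgError(
                f"weighted Gram matrix for component {g} is singular "
                f"(rank {rank} < {p})"
            ) from err
        if has_rand:
            num = np.zeros((r, r))
            for j, grp in enumerate(es.groups):
                t = es.tau[grp.idx, g]
                mom = es.moments[g][j]
                num += np.einsum(
                    "m,mr,ms->rs", t, mom.bhat, mom.bhat
                ) + np.einsum("m,mrs->rs", t, mom.Bcov)
            Psi[g] = num / S_tau[g]

    # residual variances at the updated alpha
    s2_num = np.zeros(G)
    s2_den = np.zeros(G)
    for g in range(G):
        for j, grp in enumerate(es.groups):
            t = es.tau[grp.idx, g]
            mom = es.moments[g][j]
            res = mom.yhat - grp.X @ alpha[g]
            if has_rand:
                res = res - mom.bhat @ grp.Z.T
            ess = (
                np.einsum("mn,mn->m", res, res)
                + mom.tr_Omega + mom.tr_ZBZ - 2.0 * mom.tr_YBZ
            )
            s2_num[g] += float(t @ ess)
            s2_den[g] += t.sum() * grp.n
    if spec.equal_residual_variance:
        sigma2 = np.full(G, s2_num.sum() / s2_den.sum())
    else:
        sigma2 = s2_num / s2_den

    if has_rand:
        if spec.equal_random_variance:
            pooled = np.einsum("g,grs->rs", S_tau, Psi) / N
            Psi = np.repeat(pooled[None], G, axis=0)
        Psi = np.stack([_repair_psd(Psi[g], f"Psi[{g}]") for g in range(G)])

    return Parameters(pi=pi, alpha=alpha, sigma2=sigma2, Psi=Psi)


def expected_complete_loglik(
    data: Dataset, es: EStepResult, params: Parameters, spec: ModelSpec
) -> float:
    """Q-function: expected complete log-likelihood at ``params``."""
    G = es.tau.shape[1]
    has_rand = params.Psi is not None and es.moments[0][0].bhat is not None
    total = 0.0
    for g in range(G):
        lp = np.log(params.pi[g])
        s2 = params.sigma2[g]
        if has_rand:
            Psi_g = params.Psi[g]
            sign, logdetP = np.linalg.slogdet(Psi_g)
            if sign <= 0:
                return -np.inf
            Pinv = np.linalg.inv(Psi_g)
        for j, grp in enumerate(es.groups):
            t = es.tau[grp.idx, g]
            mom = es.moments[g][j]
            res = mom.yhat - grp.X @ params.alpha[g]
            if has_rand:
                res = res - mom.bhat @ grp.Z.T
            ess = (
                np.einsum("mn,mn->m", res, res)
                + mom.tr_Omega + mom.tr_ZBZ - 2.0 * mom.tr_YBZ
            )
            contrib = lp - 0.5 * grp.n * (_LOG_2PI + np.log(s2)) - ess / (2 * s2)
            if has_rand:
                Ebb = np.einsum("mr,ms->mrs", mom.bhat, mom.bhat) + mom.Bcov
                quad = np.einsum("rs,msr->m", Pinv, Ebb)
                contrib = contrib - 0.5 * (
                    Psi_g.shape[0] * _LOG_2PI + logdetP + quad
                )
            total += float(t @ contrib)
    return total


# ---------------------------------------------------------------------------
# initialization and multi-start driver
# ---------------------------------------------------------------------------


def _weighted_mstep_init(data: Dataset, spec: ModelSpec, tau: np.ndarray) -> Parameters:
    """Starting parameters from (hard or soft) assignments.

    Censored values sit at their limits and random effects at zero for the
    alpha/sigma2 updates; Psi is seeded from the between-individual variance
    of per-individual mean residuals (a zero Psi would be absorbing under
    the E-step formulas, so the literal zero-random-effect update is not
    usable for it).
    """
    G = tau.shape[1]
    p = data[0].X.shape[1]
    r = 0 if data[0].Z is None else data[0].Z.shape[1]
    alpha = np.zeros((G, p))
    sigma2 = np.zeros(G)
    Psi = np.zeros((G, r, r)) if spec.has_random and r else None
    for g in range(G):
        gram = np.zeros((p, p))
        rhs = np.zeros(p)
        for i, ind in enumerate(data):
            gram += tau[i, g] * (ind.X.T @ ind.X)
            rhs += tau[i, g] * (ind.X.T @ ind.q)
        alpha[g] = np.linalg.solve(gram + 1e-8 * np.eye(p), rhs)
        num = den = 0.0
        means = np.zeros(data.N)
        for i, ind in enumerate(data):
            res = ind.q - ind.X @ alpha[g]
            num += tau[i, g] * float(res @ res)
            den += tau[i, g] * ind.n
            means[i] = res.mean()
        sigma2[g] = max(num / den, 1e-8)
        if Psi is not None:
            w = tau[:, g] / tau[:, g].sum()
            mbar = float(w @ means)
            v = float(w @ (means - mbar) ** 2)
            Psi[g] = max(v, 0.1 * sigma2[g]) * np.eye(r)
    pi = np.maximum(tau.mean(axis=0), 1e-6)
    pi = pi / pi.sum()
    if spec.equal_residual_variance:
        sigma2 = np.full(G, sigma2.mean())
    if Psi is not None and spec.equal_random_variance:
        Psi = np.repeat(Psi.mean(axis=0)[None], G, axis=0)
    return Parameters(pi=pi, alpha=alpha, sigma2=sigma2, Psi=Psi)


def initialize(
    data: Dataset, spec: ModelSpec, rng: np.random.Generator,
    init_tau: np.ndarray | None = None,
) -> Parameters:
    """Starting parameters from a random partition (or given posteriors).

    Individuals are partitioned uniformly into G groups; a partition leaving
    any group with fewer than two individuals (one, for very small samples)
    is redrawn up to 100 times.
    """
    G = spec.G
    if init_tau is not None:
        return _weighted_mstep_init(data, spec, np.asarray(init_tau, float))
    if G == 1:
        return _weighted_mstep_init(data, spec, np.ones((data.N, 1)))
    min_size = 2 if data.N >= 2 * G else 1
    for _ in range(100):
        assign = rng.integers(0, G, size=data.N)
        counts = np.bincount(assign, minlength=G)
        if counts.min() >= min_size:
            tau = np.zeros((data.N, G))
            tau[np.arange(data.N), assign] = 1.0
            return _weighted_mstep_init(data, spec, tau)
    raise RuntimeError(
        f"could not draw a partition of {data.N} individuals into {G} groups "
        f"with at least {min_size} members each in 100 attempts"
    )


@dataclass
class FitResult:
    """Converged EM fit: parameters, likelihood path and posteriors."""

    params: Parameters
    loglik: float
    trace: np.ndarray
    tau: np.ndarray
    niter: int
    converged: bool
    seed: int | None
    spec: ModelSpec
    N: int
    p: int
    r: int
    diagnostics: list = field(default_factory=list)
    spline: object | None = None  # SplineSpec used to build the fixed design

    @property
    def n_params(self) -> int:
        from .core import count_parameters

        return count_parameters(self.spec, self.p, self.r)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.N)


def _run_chain(data, spec, params, control, groups):
    trace = []
    prev = None
    converged = False
    es = None
    for _ in range(control.max_iter):
        es = e_step(
            data, params, groups=groups,
            starvation_floor=control.starvation_floor,
        )
        ll = es.loglik
        trace.append(ll)
        if prev is not None and abs(ll - prev) / max(abs(prev), 1e-300) < control.tol:
            converged = True
            break
        params = m_step(data, es, spec)
        prev = ll
    return params, trace, converged, es


def fit(
    data: Dataset,
    spec: ModelSpec,
    control: EMControl | None = None,
    *,
    init_tau: np.ndarray | None = None,
) -> FitResult:
    """Multi-start EM: best of ``control.n_starts`` random initialisations.

    When ``init_tau`` is given, a single chain is started from those
    posterior probabilities instead (used by the two-stage selection).
    """
    control = control or EMControl()
    groups = make_groups(data)
    rng = np.random.default_rng(control.seed)
    p = data[0].X.shape[1]
    r = 0 if data[0].Z is None else data[0].Z.shape[1]

    n_chains = 1 if init_tau is not None else (
        1 if spec.G == 1 else control.n_starts
    )
    best = None
    diagnostics = []
    for chain in range(n_chains):
        try:
            params0 = initialize(data, spec, rng, init_tau=init_tau)
            params, trace, converged, es = _run_chain(
                data, spec, params0, control, groups
            )
        except (ComponentStarvationError, np.linalg.LinAlgError) as err:
            diagnostics.append({"chain": chain, "error": str(err)})
            logger.info("EM chain %d aborted: %s", chain, err)
            continue
        diagnostics.append(
            {"chain": chain, "loglik": trace[-1], "niter": len(trace),
             "converged": converged}
        )
        if best is None or trace[-1] > best[1][-1]:
            best = (params, trace, converged, es)
    if best is None:
        raise AllChainsFailedError(diagnostics)
    params, trace, converged, es = best
    return FitResult(
        params=params, loglik=trace[-1], trace=np.asarray(trace),
        tau=es.tau, niter=len(trace), converged=converged,
        seed=control.seed, spec=spec, N=data.N, p=p, r=r,
        diagnostics=diagnostics, spline=data.spline,
    )
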