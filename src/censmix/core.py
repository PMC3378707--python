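"""Data containers and observed-data likelihood for censored LMM mixtures.

The model: each individual i (with n_i repeated measurements) belongs to one
of G latent components; within component g,

    Y_i = X_i alpha_g + Z_i beta_i + e_i,
    beta_i ~ N(0, Psi_g),   e_i ~ N(0, sigma2_g I),

so marginally Y_i ~ N(X_i alpha_g, Z_i Psi_g Z_i' + sigma2_g I) given
membership.  The response may be left-censored at a detection limit: for a
censored occasion the recorded value ``q_ij`` is the limit and the indicator
``c_ij = 1``.  The observed-data likelihood of an individual under component
g therefore factors into the Gaussian density of the uncensored coordinates
times the conditional multivariate-normal CDF of the censored block at its
limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from . import tmvn
from .splines import SplineSpec, build_basis

__all__ = [
    "ModelSpec",
    "Parameters",
    "IndividualData",
    "ComponentMarginal",
    "Dataset",
    "marginal_moments",
    "component_loglik",
    "observed_loglik",
    "count_parameters",
]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of a mixture of linear mixed models.

    Parameters
    ----------
    G : int
        Number of mixture components (>= 1).
    random_intercept : bool
        Whether a random intercept per individual is included.  Explicit
        random-effects design matrices of higher dimension may be attached
        directly to the data; this flag then simply records their presence.
    equal_residual_variance : bool
        Constrain sigma2_g to be identical across components.
    equal_random_variance : bool
        Constrain Psi_g to be identical across components (ignored without
        random effects).
    spline_df : int or None
        Degrees of freedom of the B-spline time basis when the fixed design
        is built from observation times; None when design matrices are
        supplied explicitly.
    """

    G: int
    random_intercept: bool = True
    equal_residual_variance: bool = False
    equal_random_variance: bool = False
    spline_df: int | None = None

    def __post_init__(self):
        if self.G < 1:
            raise ValueError("G must be >= 1")

    @property
    def has_random(self) -> bool:
        return self.random_intercept

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "random_intercept": self.random_intercept,
            "equal_residual_variance": self.equal_residual_variance,
            "equal_random_variance": self.equal_random_variance,
            "spline_df": self.spline_df,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class Parameters:
    """Mixture parameters Theta = (pi_g, alpha_g, sigma2_g, Psi_g)_{g=1..G}.

    ``alpha`` is (G, p); ``Psi`` is (G, r, r) or None when the model carries
    no random effects.  Under the equality constraints the repeated blocks
    are stored expanded (identical across g).
    """

    pi: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    Psi: np.ndarray | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        self.alpha = np.atleast_2d(np.asarray(self.alpha, float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, float))
        if self.Psi is not None:
            self.Psi = np.asarray(self.Psi, float)
            if self.Psi.ndim == 2:
                self.Psi = np.repeat(self.Psi[None], self.G, axis=0)

    @property
    def G(self) -> int:
        return len(self.pi)

    @property
    def p(self) -> int:
        return self.alpha.shape[1]

    @property
    def r(self) -> int:
        return 0 if self.Psi is None else self.Psi.shape[1]

    def validate(self, spec: ModelSpec | None = None, tol: float = 1e-10) -> None:
        if np.any(self.pi <= 0):
            raise ValueError("component weights must be strictly positive")
        if abs(self.pi.sum() - 1.0) > tol:
            raise ValueError(f"component weights sum to {self.pi.sum()}, not 1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("residual variances must be positive")
        if self.alpha.shape[0] != self.G or self.sigma2.shape[0] != self.G:
            raise ValueError("per-component blocks must have length G")
        if self.Psi is not None:
            for g in range(self.G):
                P = self.Psi[g]
                if not np.allclose(P, P.T, atol=1e-10):
                    raise ValueError(f"Psi[{g}] is not symmetric")
                if np.linalg.eigvalsh(P)[0] < -1e-10:
                    raise ValueError(f"Psi[{g}] is not positive semidefinite")
        if spec is not None:
            if spec.equal_residual_variance and not np.allclose(
                self.sigma2, self.sigma2[0]
            ):
                raise ValueError("equal_residual_variance violated")
            if (
                spec.has_random
                and spec.equal_random_variance
                and self.Psi is not None
                and not all(np.allclose(P, self.Psi[0]) for P in self.Psi)
            ):
                raise ValueError("equal_random_variance violated")

    def permuted(self, perm) -> "Parameters":
        """Relabel the components according to ``perm`` (new[g] = old[perm[g]])."""
        perm = np.asarray(perm, int)
        return Parameters(
            pi=self.pi[perm],
            alpha=self.alpha[perm],
            sigma2=self.sigma2[perm],
            Psi=None if self.Psi is None else self.Psi[perm],
        )

    def copy(self) -> "Parameters":
        return Parameters(
            pi=self.pi.copy(),
            alpha=self.alpha.copy(),
            sigma2=self.sigma2.copy(),
            Psi=None if self.Psi is None else self.Psi.copy(),
        )


@dataclass
class IndividualData:
    """One individual's (possibly censored) trajectory and design matrices.

    ``q`` records the response; for censored occasions (``c = 1``) it holds
    the detection limit on the response scale.
    """

    id: object
    q: np.ndarray
    c: np.ndarray
    X: np.ndarray | None = None
    Z: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, float))
        self.c = np.atleast_1d(np.asarray(self.c, int))
        if self.times is not None:
            self.times = np.atleast_1d(np.asarray(self.times, float))
        n = self.q.shape[0]
        if n < 1:
            raise ValueError(f"individual {self.id}: needs n_i >= 1")
        if self.c.shape[0] != n:
            raise ValueError(f"individual {self.id}: q and c lengths differ")
        if not np.all(np.isin(self.c, [0, 1])):
            raise ValueError(f"individual {self.id}: censoring indicators not 0/1")
        for name, M in (("X", self.X), ("Z", self.Z)):
            if M is not None:
                M = np.atleast_2d(np.asarray(M, float))
                if M.shape[0] != n:
                    raise ValueError(
                        f"individual {self.id}: {name} has {M.shape[0]} rows, "
                        f"expected {n}"
                    )
                setattr(self, name, M)

    @property
    def n(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class ComponentMarginal:
    """Marginal mean and covariance of Y_i under one component."""

    mu: np.ndarray
    V: np.ndarray


@dataclass
class Dataset:
    """Ordered collection of individuals with unique ids."""

    individuals: list
    spline: SplineSpec | None = field(default=None)

    def __post_init__(self):
        if len(self.individuals) < 1:
            raise ValueError("dataset must contain at least one individual")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")

    @property
    def N(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, i):
        return self.individuals[i]

    def all_times(self) -> np.ndarray:
        return np.concatenate([ind.times for ind in self.individuals])

    def with_designs(self, spline: SplineSpec, random_intercept: bool) -> "Dataset":
        """Attach spline fixed designs (and a random-intercept column)."""
        inds = []
        for ind in self.individuals:
            if ind.times is None:
                raise ValueError(f"individual {ind.id} has no observation times")
            X = build_basis(ind.times, spline)
            Z = np.ones((ind.n, 1)) if random_intercept else None
            inds.append(replace(ind, X=X, Z=Z))
        return Dataset(individuals=inds, spline=spline)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def marginal_moments(ind: IndividualData, params: Parameters, g: int) -> ComponentMarginal:
    """Marginal moments of Y_i under component g (0-based index)."""
    if not 0 <= g < params.G:
        raise ValueError(f"component index {g} outside 0..{params.G - 1}")
    if ind.X is None:
        raise ValueError(f"individual {ind.id}: no fixed design matrix")
    if ind.X.shape[1] != params.p:
        raise ValueError(
            f"individual {ind.id}: X has {ind.X.shape[1]} columns, "
            f"parameters have p={params.p}"
        )
    mu = ind.X @ params.alpha[g]
    V = params.sigma2[g] * np.eye(ind.n)
    if ind.Z is not None and params.Psi is not None:
        if ind.Z.shape[1] != params.r:
            raise ValueError(
                f"individual {ind.id}: Z has {ind.Z.shape[1]} columns, "
                f"parameters have r={params.r}"
            )
        V = V + ind.Z @ params.Psi[g] @ ind.Z.T
    return ComponentMarginal(mu=mu, V=V)


def _mvn_logpdf(x: np.ndarray, mu: np.ndarray, V: np.ndarray) -> float:
    n = x.shape[0]
    cf = cho_factor(V, lower=True)
    dev = x - mu
    maha = dev @ cho_solve(cf, dev)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (n * _LOG_2PI + logdet + maha))


def component_loglik(ind: IndividualData, params: Parameters, g: int) -> float:
    """Observed-data log-likelihood contribution of one individual/component.

    Uncensored coordinates contribute their joint Gaussian density; censored
    coordinates contribute the conditional MVN CDF at the detection limits
    given the uncensored ones.  A CDF value that underflows is clamped at a
    tiny floor and the event logged.
    """
    if not np.all(np.isfinite(ind.q)):
        raise ValueError(f"individual {ind.id}: non-finite responses")
    marg = marginal_moments(ind, params, g)
    obs = np.where(ind.c == 0)[0]
    cen = np.where(ind.c == 1)[0]
    ll = 0.0
    if obs.size:
        ll += _mvn_logpdf(ind.q[obs], marg.mu[obs], marg.V[np.ix_(obs, obs)])
    if cen.size:
        if obs.size:
            Voo = marg.V[np.ix_(obs, obs)]
            Vco = marg.V[np.ix_(cen, obs)]
            sol = np.linalg.solve(Voo, ind.q[obs] - marg.mu[obs])
            cmean = marg.mu[cen] + Vco @ sol
            ccov = marg.V[np.ix_(cen, cen)] - Vco @ np.linalg.solve(Voo, Vco.T)
            ccov = 0.5 * (ccov + ccov.T)
        else:
            cmean = marg.mu[cen]
            ccov = marg.V[np.ix_(cen, cen)]
        prob = tmvn.mvn_cdf(ind.q[cen], cmean, ccov)
        if prob <= tmvn.LOG_FLOOR:
            logger.warning(
                "individual %s component %d: censored-block CDF underflow, "
                "clamped to %.0e", ind.id, g, tmvn.LOG_FLOOR,
            )
            prob = tmvn.LOG_FLOOR
        ll += float(np.log(prob))
    return ll


def component_logliks(data: Dataset, params: Parameters) -> np.ndarray:
    """N x G matrix of per-individual, per-component log-likelihoods."""
    return np.array(
        [[component_loglik(ind, params, g) for g in range(params.G)] for ind in data]
    )


def observed_loglik(data: Dataset, params: Parameters) -> float:
    """Observed-data log-likelihood of the mixture (log-sum-exp stabilised)."""
    L = component_logliks(data, params)
    return float(np.sum(logsumexp(L + np.log(params.pi)[None, :], axis=1)))


def count_parameters(spec: ModelSpec, p: int, r: int) -> int:
    """Number of free parameters of the (possibly constrained) model."""
    if p < 1 or r < 0:
        raise ValueError("need p >= 1 and r >= 0")
    k = (spec.G - 1) + spec.G * p
    k += 1 if spec.equal_residual_variance else spec.G
    if spec.has_random and r > 0:
        blocks = 1 if spec.equal_random_variance else spec.G
        k += blocks * (r * (r + 1)) // 2
    return k
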