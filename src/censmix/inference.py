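"""Score vectors, empirical information and confidence bands.

Standard errors come from the empirical (outer-product-of-gradients)
information matrix: with per-individual score vectors s_i evaluated at the
maximum-likelihood estimate, I = sum_i s_i s_i' and se = sqrt(diag(I^-1)).

The observed-data scores are computed analytically through Fisher's
identity: the gradient of the observed log-likelihood equals the posterior
expectation of the complete-data score, so every block reuses the E-step's
truncated-moment quantities:

    d l_i / d alpha_g   = tau_ig X_i'(yhat_ig - X_i alpha_g - Z_i bhat_ig) / sigma2_g
    d l_i / d sigma2_g  = tau_ig ( -n_i / (2 sigma2_g) + E||e_i||^2 / (2 sigma2_g^2) )
    d l_i / d Psi_g     = tau_ig ( -Psi_g^-1 + Psi_g^-1 E[beta beta'] Psi_g^-1 ) / 2
    d l_i / d pi_g      = tau_ig / pi_g - tau_iG / pi_G      (free simplex chart)

with off-diagonal vech(Psi) entries doubled (both symmetric copies move).
Under the equality constraints the corresponding blocks are summed over
components.  Finite differences of the observed log-likelihood serve as an
independent correctness gate in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import em
from .core import Dataset, ModelSpec, Parameters
from .splines import SplineSpec, build_basis

__all__ = [
    "ParamIndex",
    "InformationResult",
    "score_vectors",
    "standard_errors",
    "mean_band",
]

logger = logging.getLogger(__name__)


class ParamIndex:
    """Chart of free parameters: names and block slices.

    Order: pi_1..pi_{G-1}, alpha blocks per component, residual variance
    block(s), vech(Psi) block(s).
    """

    def __init__(self, spec: ModelSpec, p: int, r: int):
        self.spec = spec
        self.p = p
        self.r = r
        G = spec.G
        names: list = []
        names += [f"pi[{g}]" for g in range(G - 1)]
        self.alpha_slices = []
        for g in range(G):
            start = len(names)
            names += [f"alpha[{g}][{j}]" for j in range(p)]
            self.alpha_slices.append(slice(start, len(names)))
        start = len(names)
        if spec.equal_residual_variance:
            names += ["sigma2"]
            self.sigma2_slices = [slice(start, start + 1)] * G
        else:
            names += [f"sigma2[{g}]" for g in range(G)]
            self.sigma2_slices = [slice(start + g, start + g + 1) for g in range(G)]
        self.psi_slices = []
        self.has_random = spec.has_random and r > 0
        if self.has_random:
            nv = (r * (r + 1)) // 2
            rows, cols = np.tril_indices(r)
            if spec.equal_random_variance:
                start = len(names)
                names += [f"Psi[{int(k)},{int(l)}]" for k, l in zip(rows, cols)]
                self.psi_slices = [slice(start, start + nv)] * G
            else:
                for g in range(G):
                    start = len(names)
                    names += [
                        f"Psi[{g}][{int(k)},{int(l)}]" for k, l in zip(rows, cols)
                    ]
                    self.psi_slices.append(slice(start, start + nv))
        self.names = names
        self.k = len(names)
        self.pi_slice = slice(0, G - 1)

    def pack(self, params: Parameters) -> np.ndarray:
        theta = np.empty(self.k)
        G = self.spec.G
        theta[self.pi_slice] = params.pi[: G - 1]
        for g in range(G):
            theta[self.alpha_slices[g]] = params.alpha[g]
        for g in range(G):
            theta[self.sigma2_slices[g]] = params.sigma2[g]
        if self.has_random:
            rows, cols = np.tril_indices(self.r)
            for g in range(G):
                theta[self.psi_slices[g]] = params.Psi[g][rows, cols]
        return theta

    def unpack(self, theta: np.ndarray) -> Parameters:
        G = self.spec.G
        pi_free = theta[self.pi_slice]
        pi = np.concatenate([pi_free, [1.0 - pi_free.sum()]])
        alpha = np.stack([theta[self.alpha_slices[g]] for g in range(G)])
        sigma2 = np.array([theta[self.sigma2_slices[g]][0] for g in range(G)])
        Psi = None
        if self.has_random:
            rows, cols = np.tril_indices(self.r)
            Psi = np.zeros((G, self.r, self.r))
            for g in range(G):
                Psi[g][rows, cols] = theta[self.psi_slices[g]]
                Psi[g][cols, rows] = Psi[g][rows, cols]
        return Parameters(pi=pi, alpha=alpha, sigma2=sigma2, Psi=Psi)


@dataclass
class InformationResult:
    """Per-individual scores, empirical information and standard errors."""

    scores: np.ndarray  # (N, k)
    info: np.ndarray  # (k, k)
    se: np.ndarray  # (k,)
    cov: np.ndarray  # (k, k) inverse (or pseudo-inverse) of info
    index: ParamIndex
    pseudo_inverse: bool = False

    def alpha_cov(self, g: int) -> np.ndarray:
        sl = self.index.alpha_slices[g]
        return self.cov[sl, sl]


def score_vectors(
    data: Dataset,
    params: Parameters,
    spec: ModelSpec,
    es: em.EStepResult | None = None,
) -> np.ndarray:
    """N x k matrix of per-individual observed-data score contributions."""
    if es is None:
        es = em.e_step(data, params)
    G = params.G
    p, r = params.p, params.r
    index = ParamIndex(spec, p, r)
    N = data.N
    scores = np.zeros((N, index.k))

    tau = es.tau
    # component-weight block on the free chart (first G-1 weights)
    if G > 1:
        scores[:, index.pi_slice] = (
            tau[:, : G - 1] / params.pi[: G - 1]
            - (tau[:, G - 1] / params.pi[G - 1])[:, None]
        )

    has_rand = index.has_random and es.moments[0][0].bhat is not None
    for g in range(G):
        s2 = params.sigma2[g]
        if has_rand:
            Pinv = np.linalg.inv(params.Psi[g])
        for j, grp in enumerate(es.groups):
            idx = grp.idx
            t = tau[idx, g]
            mom = es.moments[g][j]
            res = mom.yhat - grp.X @ params.alpha[g]
            if has_rand:
                res = res - mom.bhat @ grp.Z.T
            scores[idx, index.alpha_slices[g]] += (
                t[:, None] * (res @ grp.X) / s2
            )
            ess = (
                np.einsum("mn,mn->m", res, res)
                + mom.tr_Omega + mom.tr_ZBZ - 2.0 * mom.tr_YBZ
            )
            scores[idx, index.sigma2_slices[g]] += (
                t * (-grp.n / (2.0 * s2) + ess / (2.0 * s2 * s2))
            )[:, None]
            if has_rand:
                Ebb = np.einsum("mr,ms->mrs", mom.bhat, mom.bhat) + mom.Bcov
                Smat = 0.5 * (
                    np.einsum("rs,mst,tu->mru", Pinv, Ebb, Pinv) - Pinv[None]
                )
                # vech chart: off-diagonal entries appear twice in Psi
                D = 2.0 * Smat
                D[:, np.arange(r), np.arange(r)] = Smat[
                    :, np.arange(r), np.arange(r)
                ]
                rows, cols = np.tril_indices(r)
                scores[idx, index.psi_slices[g]] += t[:, None] * D[:, rows, cols]
    if not np.all(np.isfinite(scores)):
        bad = np.where(~np.isfinite(scores))
        raise FloatingPointError(
            f"non-finite score for individual {data[bad[0][0]].id}, "
            f"parameter {index.names[bad[1][0]]}"
        )
    return scores


def standard_errors(data: Dataset, fit: em.FitResult) -> InformationResult:
    """Empirical-information standard errors at a converged fit."""
    index = ParamIndex(fit.spec, fit.p, fit.r)
    scores = score_vectors(data, fit.params, fit.spec)
    info = scores.T @ scores
    info = 0.5 * (info + info.T)
    pseudo = False
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError("inverse unusable")
    except np.linalg.LinAlgError:
        logger.warning(
            "empirical information numerically singular; using pseudo-inverse"
        )
        cov = np.linalg.pinv(info, rcond=1e-12)
        pseudo = True
        if not np.all(np.isfinite(cov)):
            raise
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return InformationResult(
        scores=scores, info=info, se=se, cov=cov, index=index,
        pseudo_inverse=pseudo,
    )


def mean_band(
    fit: em.FitResult,
    info: InformationResult,
    g: int,
    times,
    level: float = 0.95,
    spline: SplineSpec | None = None,
):
    """Pointwise confidence band for the component-g mean trajectory.

    Returns ``(lower, mean, upper)`` arrays:  m_g(t) +/- z * sqrt(b(t)'
    Cov(alpha_g) b(t)) with b(t) the spline design row at t.
    """
    spline = spline or fit.spline
    if spline is None:
        raise ValueError("no spline specification available for the band")
    B = build_basis(times, spline)
    mean = B @ fit.params.alpha[g]
    C = info.alpha_cov(g)
    var = np.einsum("nj,jk,nk->n", B, C, B)
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    half = z * np.sqrt(np.maximum(var, 0.0))
    return mean - half, mean, mean + half
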