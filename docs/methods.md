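# Methods

## Model

`censmix` fits finite mixtures of Gaussian linear mixed-effects models to
longitudinal data whose response is left-censored at a detection limit.
Each individual *i* contributes repeated measurements
Y_i = X_i α_g + Z_i β_i + e_i under a latent component g drawn once per
individual with probabilities π = (π_1, …, π_G); β_i ~ N(0, Ψ_g) and
e_i ~ N(0, σ²_g I) are independent, so marginally
Y_i | g ~ N(X_i α_g, V_ig) with V_ig = Z_i Ψ_g Z_i′ + σ²_g I.  A recorded
value q_ij with censoring flag c_ij = 1 means only Y_ij ≤ q_ij is known.
The observed-data likelihood of an individual under component g is the
density of its uncensored coordinates times the conditional
multivariate-normal CDF of the censored block at its limits; the mixture
log-likelihood sums log Σ_g π_g L_ig over individuals (log-sum-exp
stabilised).

Variance parameters may be pooled across components
(`equal_residual_variance`, `equal_random_variance`); the fixed effects are
always component-specific, since the component mean trajectories are the
object of interest.  Only left censoring is supported, and component
membership is constant within an individual.

The fixed design is, by default, an explicit intercept plus a B-spline
basis in time with `df` ∈ 1..5 basis functions and polynomial degree
min(3, df).  Interior knots (df − degree of them) sit at equally spaced
quantiles of the observed times — measurement schedules in the motivating
trials are heavily front-loaded, and quantile placement puts flexibility
where the data are.  Boundary knots are the min/max of the training times;
evaluation outside them raises rather than extrapolates.  Knot placement is
a genuine free choice here (equally spaced knots are the obvious
alternative); quantile placement follows the prevailing regression-spline
convention and is recorded in the fitted model so it can be audited.

## Truncated-normal machinery

The E-step needs mean, covariance and mass of a normal vector truncated to
{x ≤ u}.  With α(u) = P(X ≤ u), F = ∂α/∂u and H = ∂²α/∂u², the moments are

    E[X | X ≤ u]   = μ − Σ F/α,
    Cov[X | X ≤ u] = Σ + Σ (H/α − F F′/α²) Σ,

algebraically equivalent to the classical closed forms: each F_k is a
univariate density times a (d−1)-dimensional CDF, each off-diagonal H_kq a
bivariate density times a (d−2)-dimensional CDF, and the diagonal
H_kk = −((u_k−μ_k)/σ_kk) F_k − Σ_{q≠k} (σ_kq/σ_kk) F_kq.

CDF backends are chosen for determinism and speed:

- d = 1: `scipy.special.ndtr` (exact).
- d = 2: a vectorised Gauss–Legendre rule on the sin-substitution integral
  (48 nodes) for |ρ| ≤ 0.925; beyond that an equal-probability-transform
  quadrature of the conditional representation with panels placed around
  the conditional sigmoid.  Verified to ≤ 5·10⁻⁷ absolute error against an
  independent high-accuracy evaluation over |ρ| ≤ 0.999.
- d = 3: reduction to the bivariate case by conditioning on one coordinate,
  integrated with a 64-node rule after mapping the outer coordinate through
  its probability transform (errors ~10⁻⁶ in the worst orthant checks).
- d ≥ 4: scipy's Genz quasi–Monte Carlo CDF with a fixed-seed generator,
  tight tolerances, so repeated evaluations are identical.

Unconstrained coordinates are encoded as `numpy.inf` and marginalised out
before any CDF call; no infinity ever enters a quadrature.  A truncation
region with mass below 10⁻¹² is treated as degenerate: the public routine
raises, while the E-step falls back to imputing censored values at their
limits with zero conditional variance and logs the event.  Probabilities
are floored at 10⁻³⁰⁰ before logs.

Inside the EM, the censored block's conditional covariance always has the
form σ²I + Z_C Ψ̃ Z_C′ (diagonal plus rank r).  Two structured paths
exploit this: with no random effects the censored coordinates are
conditionally independent and univariate formulas apply; with a random
intercept (r = 1) the rectangle mass and moments are one-dimensional
integrals over the latent factor, evaluated with an 80-node Gauss–Hermite
rule against univariate truncated-normal moments.  The factor path agrees
with the generic closed forms to ~10⁻¹⁵ at r = 1 and removes the cost
explosion for individuals with many censored occasions.  Patterns with
r ≥ 2 and more than three censored coordinates use the generic path.

## EM algorithm

Three kinds of missing data are integrated out: memberships, random
effects, censored responses.  Posterior weights are
τ_ig ∝ π_g exp(log L_ig), normalised per individual by log-sum-exp.  The
conditional moments of the censored responses come from the truncated
machinery above; the random-effects moments follow by Gaussian regression,

    b̂_ig = Ψ_g Z_i′ V_ig⁻¹ (ŷ_ig − μ_ig),
    Cov(β)_ig = Ψ_g − Ψ_g Z_i′V_ig⁻¹Z_i Ψ_g + Ψ_g Z_i′V_ig⁻¹ Ω_ig V_ig⁻¹Z_i Ψ_g,
    Cov(Y, β)_ig = Ω_ig V_ig⁻¹ Z_i Ψ_g,

with Ω_ig the conditional covariance of Y (nonzero only on the censored
block).  The M-step is closed-form: π from mean responsibilities, α_g by
responsibility-weighted least squares on ŷ − Z b̂, Ψ_g from the expected
second moments of β, and σ²_g from the expected residual sum of squares

    E‖e‖² = ‖ŷ − Xα − Z b̂‖² + tr Ω + tr(Z Cov(β) Z′) − 2 tr(Cov(Y, β) Z′)

evaluated at the updated α (an ECM-style ordering; the ascent of the
observed log-likelihood is asserted by test on every fitted trace rather
than proved).  The cross-covariance term is essential — dropping it breaks
the Monte-Carlo agreement of the σ² update.  Under the equality
constraints the corresponding sums pool over components before
normalising.  A Ψ update that drifts slightly indefinite is repaired by
clipping its eigenvalues at zero (logged).

Individuals are grouped by identical (X, Z, censoring pattern); all
factorisations are shared within a group and the truncated-moment work is
vectorised across its members, which is what makes hundreds of EM fits per
test run affordable.

**Initialisation.** Individuals are partitioned uniformly at random into G
groups (partitions leaving a group with fewer than two members are redrawn,
up to 100 times); censored values start at their limits and random effects
at zero, and a weighted least-squares M-step yields starting α, σ², π.
Ψ cannot be initialised from the literal zero-random-effects update: that
gives Ψ = 0, which the E-step formulas make absorbing (b̂ ≡ 0 forever).
Instead Ψ starts at the between-individual variance of per-individual mean
residuals, floored at 0.1 σ².  Multi-start: `n_starts` chains (default 5)
from different random partitions; the chain with the highest final
log-likelihood wins.  A chain aborts when some component's total
responsibility falls below 10⁻⁶ N ("starvation") or an update goes
singular; only a run in which every chain aborts raises.

**Convergence.** A chain stops when the relative change in log-likelihood
between iterations drops below `tol` (default 10⁻⁶) or after `max_iter`
(default 2000) iterations.  Every source of randomness — partitions and
per-chain behaviour — flows from a single integer seed.

## Model selection

The grid crosses G (default 1–5), spline df (1–5), the two variance
constraints, and the presence of the random intercept; each cell is fitted
with the shared control and ranked by AIC = −2ℓ + 2k and
BIC = −2ℓ + k log N.  The sample size in the BIC penalty is the number of
individuals, not observations: individuals are the independent,
exchangeable units of the mixture.  This choice is recorded in the output
table so a user can recompute with the other convention.  Non-converged
cells are kept in the table but excluded from best-model selection.
Per-cell seeds derive deterministically from the master seed and the cell
index.

The two-stage shortcut first selects (G, df) among unrestricted-variance
models by BIC, then compares the constraint variants at the winning
(G, df), warm-starting each constrained EM from the stage-1 posterior
probabilities.

## Inference

Standard errors use the empirical (outer-product-of-gradients) information
I = Σ_i s_i s_i′.  Per-individual scores are analytic, via Fisher's
identity: the observed-data score equals the posterior expectation of the
complete-data score, so every block reuses the E-step moments (α block:
τ X′(ŷ − Xα − Zb̂)/σ²; σ² block from E‖e‖²; Ψ block from
Ψ⁻¹(E[ββ′] − Ψ)Ψ⁻¹/2 with off-diagonal vech entries doubled; π on the
free (G−1)-weight chart).  Central finite differences of the observed
log-likelihood act as the correctness gate in the test suite (relative
agreement ≤ 10⁻³ under ~30% censoring).  A numerically singular
information matrix falls back to a pseudo-inverse with a warning.
Pointwise 1−a confidence bands for a component mean are
b(t)′α_g ± z · sqrt(b(t)′ Cov(α_g) b(t)).

## Synthetic data

The generator draws from the model exactly: membership, random intercept,
residuals, then left-censoring at the limit.  The default two-component
design emulates a viral-load trial on the log₁₀ scale: schedule
{0, 2, 7, 14, 28, 56, 112, 168} days (dense early), detection limit 2.0
(100 copies/ml), quadratic-spline means with one component declining from
~4.5 to ~1.0 (crossing the limit) and one dipping to ~2.0 before
rebounding to ~3.3, weights (0.55, 0.45), residual sd 0.55, random-
intercept sd 0.4.  These values give an expected censored fraction of
~20%, comparable to such trials.  What the generator does **not** emulate:
missed visits and dropout, assay-dependent limits, non-Gaussian residuals,
or membership that drifts over time — passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
their violation.

The parametric bootstrap resimulates from a design (or fitted model),
refits — optionally with grid selection — matches estimated to generating
components, and scores agreement with the adjusted Rand index.  Matching
maximises assignment agreement over label permutations (exhaustively for
G ≤ 6, so ties resolve to the lexicographically smallest permutation;
optimal assignment beyond).  The ARI is delegated to scikit-learn and is
cross-checked against a pair-counting implementation in the tests.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen to finish a full run in minutes on one CPU while keeping every
check statistically meaningful: rejection-sampling oracles use 10⁶ draws;
recovery and BIC-selection checks use N = 200 individuals × 8 occasions
with 20 replicates; the censoring-bias and band-calibration studies use
N = 100 with 30–50 replicates; EM controls in simulation loops use 2–3
random starts and tolerance 10⁻⁵–10⁻⁶.

## Known limitations

- Right/interval censoring are not implemented (the data structures carry
  a binary indicator only).
- Only a random intercept is exposed through the model surface; arbitrary
  Z matrices work through the library API, but censored patterns with
  r ≥ 2 and > 3 censored occasions fall back to the slower generic CDFs.
- The empirical information can be ill-conditioned when a component is
  small or the spline is locally unsupported; the pseudo-inverse fallback
  flags but does not cure this.
- EM convergence is to a local maximum; the multi-start default (5) is a
  pragmatic compromise, and hard problems may need more starts.
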