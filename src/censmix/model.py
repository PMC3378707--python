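"""Model / results surface for censored linear-mixed-model mixtures.

Usage follows the fit-object convention of the statistical-modelling
ecosystem: construct a :class:`CensoredLMMixture` from a long-format data
frame, call :meth:`~CensoredLMMixture.fit`, and read estimates, standard
errors, information criteria and component trajectories off the returned
:class:`CensoredLMMixtureResults`::

    model = CensoredLMMixture.from_dataframe(df, n_components=2, spline_df=4)
    res = model.fit(seed=1)
    print(res.summary())
    lo, mid, hi = res.mean_band(g=0, times=np.linspace(0, 168, 50))
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import em, inference
from .core import Dataset, ModelSpec, Parameters, observed_loglik
from .io import dataset_from_frame
from .splines import SplineSpec, build_basis

__all__ = ["CensoredLMMixture", "CensoredLMMixtureResults"]


class CensoredLMMixture:
    """Finite mixture of linear mixed models with left-censored responses.

    Parameters
    ----------
    data : Dataset
        Individuals with design matrices attached (see
        :meth:`Dataset.with_designs` or :meth:`from_dataframe`).
    spec : ModelSpec
        Number of components, random-effect structure and variance
        constraints.
    """

    def __init__(self, data: Dataset, spec: ModelSpec):
        for ind in data:
            if ind.X is None:
                raise ValueError(
                    f"individual {ind.id} has no design matrix; use "
                    "from_dataframe() or Dataset.with_designs()"
                )
        self.data = data
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_components: int,
        spline_df: int = 4,
        random_intercept: bool = True,
        equal_residual_variance: bool = False,
        equal_random_variance: bool = False,
        **columns,
    ) -> "CensoredLMMixture":
        """Build the model from long-format data (id, time, y, cens[, limit])."""
        raw = dataset_from_frame(df, **columns)
        spline = SplineSpec.from_times(raw.all_times(), spline_df)
        data = raw.with_designs(spline, random_intercept)
        spec = ModelSpec(
            G=n_components,
            random_intercept=random_intercept,
            equal_residual_variance=equal_residual_variance,
            equal_random_variance=equal_random_variance,
            spline_df=spline_df,
        )
        return cls(data, spec)

    def loglike(self, params: Parameters) -> float:
        """Observed-data log-likelihood at arbitrary parameter values."""
        return observed_loglik(self.data, params)

    def score_obs(self, params: Parameters) -> np.ndarray:
        """Per-individual score vectors of the observed-data log-likelihood."""
        return inference.score_vectors(self.data, params, self.spec)

    def fit(
        self,
        n_starts: int = 5,
        tol: float = 1e-6,
        max_iter: int = 2000,
        seed: int | None = None,
        init_tau: np.ndarray | None = None,
    ) -> "CensoredLMMixtureResults":
        control = em.EMControl(
            tol=tol, max_iter=max_iter, n_starts=n_starts, seed=seed
        )
        raw = em.fit(self.data, self.spec, control, init_tau=init_tau)
        return CensoredLMMixtureResults(self, raw)


class CensoredLMMixtureResults:
    """Estimates, uncertainties and diagnostics of a fitted mixture."""

    def __init__(self, model: CensoredLMMixture, raw: em.FitResult):
        self.model = model
        self.raw = raw
        self._info = None

    # -- point estimates and fit statistics --------------------------------
    @property
    def params(self) -> Parameters:
        return self.raw.params

    @property
    def llf(self) -> float:
        return self.raw.loglik

    @property
    def aic(self) -> float:
        return self.raw.aic

    @property
    def bic(self) -> float:
        return self.raw.bic

    @property
    def df_model(self) -> int:
        return self.raw.n_params

    @property
    def tau(self) -> np.ndarray:
        """Posterior component probabilities (N x G)."""
        return self.raw.tau

    @property
    def assignments(self) -> np.ndarray:
        """Maximum a posteriori component of each individual."""
        return np.argmax(self.raw.tau, axis=1)

    @property
    def converged(self) -> bool:
        return self.raw.converged

    # -- inference ----------------------------------------------------------
    @property
    def information(self) -> inference.InformationResult:
        if self._info is None:
            self._info = inference.standard_errors(self.model.data, self.raw)
        return self._info

    @property
    def bse(self) -> np.ndarray:
        """Standard errors in the free-parameter order of ``param_names``."""
        return self.information.se

    @property
    def param_names(self) -> list:
        return self.information.index.names

    def params_frame(self) -> pd.DataFrame:
        info = self.information
        theta = info.index.pack(self.params)
        return pd.DataFrame(
            {"parameter": info.index.names, "estimate": theta, "se": info.se}
        )

    def mean_curve(self, g: int, times) -> np.ndarray:
        if self.raw.spline is None:
            raise ValueError("model was built from explicit design matrices")
        return build_basis(times, self.raw.spline) @ self.params.alpha[g]

    def mean_band(self, g: int, times, level: float = 0.95):
        """Pointwise confidence band for the component-g mean trajectory."""
        return inference.mean_band(
            self.raw, self.information, g, times, level=level
        )

    # -- simulation ---------------------------------------------------------
    def simulate(self, seed: int | None = None, N: int | None = None,
                 limit: float | None = None):
        """Draw a parametric-bootstrap dataset from the fitted model."""
        from .simulate import SimDesign, simulate_dataset

        times = [ind.times for ind in self.model.data]
        if limit is None:
            cens_vals = np.concatenate(
                [ind.q[ind.c == 1] for ind in self.model.data]
            )
            limit = float(cens_vals.max()) if cens_vals.size else None
        design = SimDesign(
            params=self.params, spec=self.raw.spec, spline=self.raw.spline,
            N=N or self.raw.N,
            times=times if N in (None, self.raw.N) else times[0],
            limit=limit, seed=seed,
        )
        return simulate_dataset(design)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        p = self.params
        info = None
        try:
            info = self.information
        except Exception:  # singular information: report estimates only
            pass
        lines = []
        spec = self.raw.spec
        lines.append("Finite mixture of censored linear mixed models")
        lines.append("=" * 62)
        lines.append(
            f"components: {spec.G}    individuals: {self.raw.N}    "
            f"free parameters: {self.df_model}"
        )
        lines.append(
            f"log-likelihood: {self.llf:.4f}    AIC: {self.aic:.2f}    "
            f"BIC: {self.bic:.2f}"
        )
        lines.append(
            f"converged: {self.converged} after {self.raw.niter} iterations"
        )
        if info is not None:
            tab = self.params_frame()
            lines.append("-" * 62)
            lines.append(f"{'parameter':<20}{'estimate':>14}{'std err':>14}")
            for _, row in tab.iterrows():
                lines.append(
                    f"{row['parameter']:<20}{row['estimate']:>14.4f}"
                    f"{row['se']:>14.4f}"
                )
        else:
            lines.append("(standard errors unavailable: singular information)")
            lines.append(f"pi: {np.array2string(p.pi, precision=4)}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<CensoredLMMixtureResults G={self.raw.spec.G} "
            f"llf={self.llf:.2f} converged={self.converged}>"
        )
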