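"""Model-grid fitting and information-criterion selection.

The candidate space crosses the number of components G, the flexibility of
the B-spline time basis (df), the presence of a random intercept, and
equality constraints on the residual and random-effect variances.  Every
cell is fitted by multi-start EM and ranked by BIC (recommended for
selecting G) and AIC, with the sample size in the BIC penalty taken as the
number of individuals — the independent units of the mixture.

A two-stage shortcut is provided: stage one searches (G, df) among the
unrestricted-variance models only; stage two holds the winning (G, df)
fixed and compares the variance-constraint variants, warm-starting each EM
from the stage-one posterior probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Dataset, ModelSpec
from .em import EMControl, FitResult, fit
from .splines import SplineSpec

__all__ = ["ModelGrid", "ModelCell", "SelectionResult", "fit_grid", "two_stage_select"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelCell:
    """One candidate model: spline df plus the mixture spec."""

    G: int
    df: int
    random_intercept: bool
    equal_residual_variance: bool
    equal_random_variance: bool

    def spec(self) -> ModelSpec:
        return ModelSpec(
            G=self.G,
            random_intercept=self.random_intercept,
            equal_residual_variance=self.equal_residual_variance,
            equal_random_variance=self.equal_random_variance,
            spline_df=self.df,
        )


def _choices(kind: str, what: str):
    table = {
        "equal": [True],
        "unequal": [False],
        "both": [False, True],
    }
    if kind not in table:
        raise ValueError(f"{what} must be 'equal', 'unequal' or 'both'")
    return table[kind]


@dataclass(frozen=True)
class ModelGrid:
    """Candidate-model grid description."""

    G_values: tuple = (1, 2, 3, 4, 5)
    df_values: tuple = (1, 2, 3, 4, 5)
    residual_constraint: str = "both"
    random_constraint: str = "both"
    random_effects: str = "intercept"  # "intercept", "none" or "both"

    def __post_init__(self):
        if not self.G_values or not self.df_values:
            raise ValueError("G_values and df_values must be nonempty")
        if self.random_effects not in ("intercept", "none", "both"):
            raise ValueError("random_effects must be 'intercept', 'none' or 'both'")

    def cells(self) -> list:
        rand_opts = {
            "intercept": [True],
            "none": [False],
            "both": [True, False],
        }[self.random_effects]
        out = []
        for rand in rand_opts:
            for df in self.df_values:
                for eq_res in _choices(self.residual_constraint, "residual_constraint"):
                    psi_opts = (
                        _choices(self.random_constraint, "random_constraint")
                        if rand
                        else [False]
                    )
                    for eq_psi in psi_opts:
                        for G in self.G_values:
                            out.append(
                                ModelCell(
                                    G=G, df=df, random_intercept=rand,
                                    equal_residual_variance=eq_res,
                                    equal_random_variance=eq_psi,
                                )
                            )
        return out


@dataclass
class SelectionResult:
    """Fitted grid with per-cell criteria, sorted by BIC."""

    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)
    best_aic: ModelCell | None = None
    best_bic: ModelCell | None = None

    def best_fit(self, criterion: str = "bic") -> FitResult:
        cell = self.best_bic if criterion == "bic" else self.best_aic
        if cell is None:
            raise ValueError("no converged fits to select from")
        return self.fits[cell]


def _cell_seed(master: int | None, i: int) -> int:
    if master is None:
        master = 0
    return int((np.uint32(master) * np.uint32(100003) + np.uint32(i)) % (2**31))


def _fit_cells(data, cells, control, *, stage=None, init_taus=None):
    rows = []
    fits = {}
    for i, cell in enumerate(cells):
        spline = SplineSpec.from_times(data.all_times(), cell.df)
        designed = data.with_designs(spline, cell.random_intercept)
        ctl = replace(control, seed=_cell_seed(control.seed, i))
        init_tau = None if init_taus is None else init_taus.get(cell)
        row = {
            "G": cell.G, "df": cell.df,
            "random_intercept": cell.random_intercept,
            "equal_residual_variance": cell.equal_residual_variance,
            "equal_random_variance": cell.equal_random_variance,
        }
        if stage is not None:
            row["stage"] = stage
        try:
            res = fit(designed, cell.spec(), ctl, init_tau=init_tau)
        except Exception as err:  # recorded, not fatal
            logger.warning("grid cell %s failed: %s", cell, err)
            row.update(
                loglik=np.nan, k=np.nan, aic=np.nan, bic=np.nan,
                converged=False, niter=0, error=str(err),
            )
            rows.append(row)
            continue
        fits[cell] = res
        row.update(
            loglik=res.loglik, k=res.n_params, aic=res.aic, bic=res.bic,
            converged=res.converged, niter=res.niter, error="",
        )
        rows.append(row)
    return pd.DataFrame(rows), fits


def _pick_best(table, fits, cells_by_row):
    ok = table[table["converged"]]
    best_aic = best_bic = None
    if len(ok):
        best_aic = cells_by_row[int(ok["aic"].idxmin())]
        best_bic = cells_by_row[int(ok["bic"].idxmin())]
    return best_aic, best_bic


def fit_grid(
    data: Dataset, grid: ModelGrid, control: EMControl | None = None
) -> SelectionResult:
    """Fit every cell of the grid and rank by information criteria.

    Per-cell failures are recorded in the table (``converged = False``) and
    excluded from the best-model selection; only a fully failed grid raises.
    """
    control = control or EMControl()
    cells = grid.cells()
    table, fits = _fit_cells(data, cells, control)
    if not fits:
        raise RuntimeError("every grid cell failed to fit")
    cells_by_row = dict(enumerate(cells))
    best_aic, best_bic = _pick_best(table, fits, cells_by_row)
    order = np.argsort(table["bic"].fillna(np.inf).to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    return SelectionResult(table=table, fits=fits, best_aic=best_aic, best_bic=best_bic)


def two_stage_select(
    data: Dataset, grid: ModelGrid, control: EMControl | None = None
) -> SelectionResult:
    """Two-stage selection: (G, df) first, variance constraints second.

    Stage 1 fits the unrestricted-variance models over the (G, df) grid and
    keeps the BIC-best cell.  Stage 2 fixes that (G, df) and fits the
    requested constraint variants, each EM warm-started from the stage-1
    posterior probabilities.
    """
    control = control or EMControl()
    rand_opts = {
        "intercept": [True], "none": [False], "both": [True, False]
    }[grid.random_effects]
    stage1_cells = [
        ModelCell(G=G, df=df, random_intercept=rand,
                  equal_residual_variance=False, equal_random_variance=False)
        for rand in rand_opts for df in grid.df_values for G in grid.G_values
    ]
    t1, f1 = _fit_cells(data, stage1_cells, control, stage=1)
    cells_by_row = dict(enumerate(stage1_cells))
    _, best1 = _pick_best(t1, f1, cells_by_row)
    if best1 is None:
        raise RuntimeError("stage-1 selection failed: no converged fits")
    base_fit = f1[best1]

    stage2_cells = [
        ModelCell(G=best1.G, df=best1.df, random_intercept=best1.random_intercept,
                  equal_residual_variance=eq_res, equal_random_variance=eq_psi)
        for eq_res in _choices(grid.residual_constraint, "residual_constraint")
        for eq_psi in (
            _choices(grid.random_constraint, "random_constraint")
            if best1.random_intercept else [False]
        )
        if not (eq_res is False and eq_psi is False)  # stage-1 cell itself
    ]
    init_taus = {cell: base_fit.tau for cell in stage2_cells}
    t2, f2 = _fit_cells(data, stage2_cells, control, stage=2, init_taus=init_taus)

    table = pd.concat([t1, t2], ignore_index=True)
    fits = {**f1, **f2}
    all_cells = stage1_cells + stage2_cells
    cells_by_row = dict(enumerate(all_cells))
    best_aic, best_bic = _pick_best(table, fits, cells_by_row)
    order = np.argsort(table["bic"].fillna(np.inf).to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    return SelectionResult(table=table, fits=fits, best_aic=best_aic, best_bic=best_bic)
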