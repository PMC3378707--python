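"""Readers and writers: long-format CSV data and JSON model artifacts.

Data files are comma-separated with a header row (UTF-8): columns ``id``,
``time``, ``y``, ``cens`` (0/1) and optionally ``limit``.  For censored rows
``y`` is the detection limit; a ``limit`` column, when present, overrides
``y`` on those rows (per-assay limits).  Machine-readable outputs keep full
double precision and carry the master seed and a schema version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, IndividualData, ModelSpec, Parameters
from .em import FitResult
from .splines import SplineSpec

__all__ = [
    "read_long_csv",
    "dataset_from_frame",
    "dataset_to_frame",
    "write_dataset_csv",
    "write_fit_json",
    "read_fit_json",
    "write_results",
]

SCHEMA_VERSION = 1

REQUIRED_COLUMNS = ("id", "time", "y", "cens")


class ParseError(ValueError):
    """Structured parse failure naming the offending rows."""


def dataset_from_frame(
    df: pd.DataFrame,
    id_col: str = "id",
    time_col: str = "time",
    value_col: str = "y",
    cens_col: str = "cens",
    limit_col: str | None = None,
) -> Dataset:
    """Build a dataset (without design matrices) from a long-format frame."""
    needed = [id_col, time_col, value_col, cens_col]
    if limit_col:
        needed.append(limit_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {missing}; found {list(df.columns)}")

    cens = df[cens_col]
    bad = ~cens.isin([0, 1])
    if bad.any():
        rows = (np.where(bad)[0] + 2).tolist()[:10]  # 1-based incl. header
        raise ParseError(
            f"censoring indicator must be 0 or 1; offending file row(s): {rows}"
        )
    dup = df.duplicated(subset=[id_col, time_col], keep=False)
    if dup.any():
        rows = (np.where(dup)[0] + 2).tolist()[:10]
        raise ParseError(f"duplicate (id, time) pairs at file row(s): {rows}")
    if df[value_col].isna().any() or df[time_col].isna().any():
        rows = (np.where(df[value_col].isna() | df[time_col].isna())[0] + 2).tolist()[:10]
        raise ParseError(f"missing response/time values at file row(s): {rows}")

    individuals = []
    for key, sub in df.groupby(id_col, sort=False):
        q = sub[value_col].to_numpy(float)
        c = sub[cens_col].to_numpy(int)
        if limit_col:
            lim = sub[limit_col].to_numpy(float)
            q = np.where((c == 1) & np.isfinite(lim), lim, q)
        individuals.append(
            IndividualData(
                id=key, q=q, c=c, times=sub[time_col].to_numpy(float)
            )
        )
    return Dataset(individuals)


def read_long_csv(path, **kwargs) -> Dataset:
    """Read a long-format CSV (comma separator, header row, UTF-8)."""
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    return dataset_from_frame(df, **kwargs)


def dataset_to_frame(data: Dataset) -> pd.DataFrame:
    rows = []
    for ind in data:
        t = ind.times if ind.times is not None else np.arange(ind.n, dtype=float)
        for j in range(ind.n):
            rows.append(
                {"id": ind.id, "time": t[j], "y": ind.q[j], "cens": int(ind.c[j])}
            )
    return pd.DataFrame(rows)


def write_dataset_csv(data: Dataset, path) -> None:
    dataset_to_frame(data).to_csv(path, index=False)


def _params_to_dict(params: Parameters) -> dict:
    out = {
        "pi": params.pi.tolist(),
        "alpha": params.alpha.tolist(),
        "sigma2": params.sigma2.tolist(),
    }
    if params.Psi is not None:
        rows, cols = np.tril_indices(params.r)
        out["Psi_vech"] = [params.Psi[g][rows, cols].tolist() for g in range(params.G)]
        out["r"] = params.r
    return out


def _params_from_dict(d: dict) -> Parameters:
    Psi = None
    if "Psi_vech" in d:
        r = d["r"]
        rows, cols = np.tril_indices(r)
        G = len(d["pi"])
        Psi = np.zeros((G, r, r))
        for g in range(G):
            Psi[g][rows, cols] = d["Psi_vech"][g]
            Psi[g][cols, rows] = Psi[g][rows, cols]
    return Parameters(
        pi=np.array(d["pi"]), alpha=np.array(d["alpha"]),
        sigma2=np.array(d["sigma2"]), Psi=Psi,
    )


def write_fit_json(fit: FitResult, path) -> None:
    """Serialise a fit (spec, spline, parameters, trace, seed)."""
    from . import __version__

    doc = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "seed": fit.seed,
        "spec": fit.spec.to_dict(),
        "spline": fit.spline.to_dict() if fit.spline is not None else None,
        "params": _params_to_dict(fit.params),
        "loglik": fit.loglik,
        "trace": np.asarray(fit.trace).tolist(),
        "niter": fit.niter,
        "converged": bool(fit.converged),
        "N": fit.N,
        "p": fit.p,
        "r": fit.r,
        "tau": fit.tau.tolist(),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_fit_json(path) -> FitResult:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    spline = doc.get("spline")
    return FitResult(
        params=_params_from_dict(doc["params"]),
        loglik=doc["loglik"],
        trace=np.asarray(doc["trace"]),
        tau=np.asarray(doc["tau"]),
        niter=doc["niter"],
        converged=doc["converged"],
        seed=doc["seed"],
        spec=ModelSpec.from_dict(doc["spec"]),
        N=doc["N"],
        p=doc["p"],
        r=doc["r"],
        spline=SplineSpec.from_dict(spline) if spline else None,
    )


def write_results(obj, outdir, seed=None) -> list:
    """Write a fit / selection / bootstrap artifact; returns written paths."""
    from .selection import SelectionResult
    from .simulate import BootstrapReport

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(obj, FitResult):
        p = outdir / "model.json"
        write_fit_json(obj, p)
        written.append(p)
    elif isinstance(obj, SelectionResult):
        p = outdir / "selection.csv"
        obj.table.to_csv(p, index=False)
        written.append(p)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "seed": seed,
            "best_bic": obj.best_bic.__dict__ if obj.best_bic else None,
            "best_aic": obj.best_aic.__dict__ if obj.best_aic else None,
        }
        p = outdir / "selection.json"
        p.write_text(json.dumps(meta), encoding="utf-8")
        written.append(p)
    elif isinstance(obj, BootstrapReport):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "seed": obj.design.seed,
            "B": obj.B,
            "summary": obj.summary(),
            "replicates": obj.replicates,
        }
        p = outdir / "bootstrap.json"
        p.write_text(json.dumps(doc, default=_jsonable), encoding="utf-8")
        written.append(p)
    else:
        raise TypeError(f"don't know how to write {type(obj)!r}")
    return written


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serialisable: {type(x)!r}")
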