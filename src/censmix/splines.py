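"""B-spline design matrices for flexible mean trajectories.

The fixed-effects design is an explicit intercept plus ``df`` B-spline basis
functions of time, with the polynomial degree capped at 3 so at most cubic
splines are used (degree = min(3, df)).  Interior knots — there are
``df - degree`` of them — sit at equally spaced quantiles of the training
times, which concentrates flexibility where measurements are dense (early
follow-up in a typical trial schedule).  Boundary knots are the min/max of
the training times; evaluation outside them is an error, not extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "build_basis", "mean_curve"]

_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class SplineSpec:
    """Description of an intercept + B-spline time basis.

    Attributes
    ----------
    df : int
        Number of basis functions in addition to the intercept (1-5).
    degree : int
        Piecewise-polynomial degree, ``min(3, df)``.
    knots : tuple of float
        Interior knot positions.
    boundary : (float, float)
        Boundary knots; the valid evaluation range.
    """

    df: int
    degree: int
    knots: tuple = field(default_factory=tuple)
    boundary: tuple = (0.0, 1.0)

    def __post_init__(self):
        if not 1 <= self.df <= 5:
            raise ValueError(f"df must be in 1..5, got {self.df}")
        if self.degree != min(3, self.df):
            raise ValueError("degree must equal min(3, df)")
        if len(self.knots) != self.df - self.degree:
            raise ValueError(
                f"need {self.df - self.degree} interior knots, got {len(self.knots)}"
            )
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary must satisfy t_min < t_max")
        if any(not lo <= t <= hi for t in self.knots):
            raise ValueError("interior knots must lie within the boundary")

    @classmethod
    def from_times(cls, times, df: int) -> "SplineSpec":
        """Place interior knots at equally spaced quantiles of ``times``."""
        times = np.asarray(times, float)
        degree = min(3, df)
        n_interior = df - degree
        if n_interior > 0:
            probs = np.linspace(0, 1, n_interior + 2)[1:-1]
            knots = tuple(float(q) for q in np.quantile(times, probs))
        else:
            knots = ()
        return cls(df=df, degree=degree, knots=knots,
                   boundary=(float(times.min()), float(times.max())))

    @property
    def n_coef(self) -> int:
        """Number of fixed-effect coefficients (intercept + spline columns)."""
        return self.df + 1

    def full_knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate([
            np.repeat(lo, self.degree + 1),
            np.asarray(self.knots, float),
            np.repeat(hi, self.degree + 1),
        ])

    def to_dict(self) -> dict:
        return {"df": self.df, "degree": self.degree,
                "knots": list(self.knots), "boundary": list(self.boundary)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(df=d["df"], degree=d["degree"],
                   knots=tuple(d["knots"]), boundary=tuple(d["boundary"]))


def _full_basis(times: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """All df+1 B-spline basis functions (a partition of unity)."""
    lo, hi = spec.boundary
    if np.any(times < lo - _BOUNDARY_TOL) or np.any(times > hi + _BOUNDARY_TOL):
        bad = times[(times < lo - _BOUNDARY_TOL) | (times > hi + _BOUNDARY_TOL)]
        raise ValueError(
            f"times {bad[:5]} outside spline boundary [{lo}, {hi}]; "
            "no extrapolation is performed"
        )
    t = np.clip(times, lo, hi)
    # keep the last point inside the half-open support of design_matrix
    t = np.minimum(t, np.nextafter(hi, lo))
    kv = spec.full_knot_vector()
    B = BSpline.design_matrix(t, kv, spec.degree).toarray()
    # restore exact right-boundary values (last basis function equals 1 there)
    at_hi = times >= hi
    if np.any(at_hi):
        B[at_hi] = 0.0
        B[at_hi, -1] = 1.0
    return B


def build_basis(times, spec: SplineSpec) -> np.ndarray:
    """Design matrix: explicit intercept + df spline columns.

    The first of the df+1 basis functions is dropped to avoid collinearity
    with the intercept, mirroring the usual regression-spline convention.
    """
    times = np.atleast_1d(np.asarray(times, float))
    B = _full_basis(times, spec)
    return np.column_stack([np.ones(len(times)), B[:, 1:]])


def mean_curve(spec: SplineSpec, alpha_g, times) -> np.ndarray:
    """Component mean trajectory ``basis(times) @ alpha_g``."""
    alpha_g = np.asarray(alpha_g, float)
    if alpha_g.shape[0] != spec.n_coef:
        raise ValueError(
            f"coefficient vector has length {alpha_g.shape[0]}, "
            f"expected {spec.n_coef}"
        )
    return build_basis(times, spec) @ alpha_g
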