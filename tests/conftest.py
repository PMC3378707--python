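import logging

import numpy as np
import pytest

from censmix import (
    Dataset,
    EMControl,
    IndividualData,
    ModelSpec,
    Parameters,
    SplineSpec,
    build_basis,
)

logging.getLogger("censmix").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def times8():
    """Front-loaded 8-point schedule (days)."""
    return np.array([0.0, 2.0, 7.0, 14.0, 28.0, 56.0, 112.0, 168.0])


@pytest.fixture(scope="session")
def spline_df2(times8):
    return SplineSpec.from_times(times8, 2)


def make_mixture_data(
    N=60,
    times=None,
    spline=None,
    alpha=((4.5, -4.0, -3.5), (4.3, -4.1, -1.0)),
    pi=(0.55, 0.45),
    sigma=0.55,
    psi=0.16,
    limit=2.0,
    random_intercept=True,
    seed=0,
):
    """Simulate a small censored two-component dataset by direct sampling.

    Written out longhand (independent of censmix.simulate) so tests of the
    generator itself have something to compare against.
    """
    rng = np.random.default_rng(seed)
    times = np.array([0.0, 2.0, 7.0, 14.0, 28.0, 56.0, 112.0, 168.0]) if times is None else times
    spline = spline or SplineSpec.from_times(times, 2)
    X = build_basis(times, spline)
    alpha = np.asarray(alpha, float)
    pi = np.asarray(pi, float)
    inds, assign = [], []
    for i in range(N):
        g = rng.choice(len(pi), p=pi)
        assign.append(g)
        b = rng.normal(0.0, np.sqrt(psi)) if random_intercept else 0.0
        y = X @ alpha[g] + b + rng.normal(0.0, sigma, len(times))
        if limit is None:
            c = np.zeros(len(times), int)
            q = y
        else:
            c = (y <= limit).astype(int)
            q = np.where(c == 1, limit, y)
        Z = np.ones((len(times), 1)) if random_intercept else None
        inds.append(IndividualData(id=i, q=q, c=c, X=X, Z=Z, times=times))
    return Dataset(inds, spline=spline), np.array(assign)


@pytest.fixture(scope="session")
def censored_mixture_data():
    """N=60 two-component censored dataset with ~20% censoring."""
    return make_mixture_data(N=60, seed=11)


@pytest.fixture(scope="session")
def fast_control():
    return EMControl(tol=1e-6, max_iter=400, n_starts=2, seed=7)
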