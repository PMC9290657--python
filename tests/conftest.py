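import numpy as np
import pytest

from ltrcnet import LTRCDataset


@pytest.fixture
def toy_ltrc() -> LTRCDataset:
    """Three subjects, all events, with one delayed entry straddling t=2."""
    return LTRCDataset(
        entry=[0.0, 3.0, 1.0],
        time=[2.0, 4.0, 6.0],
        event=[1, 1, 1],
        predictors=np.zeros((3, 1)),
        predictor_names=["x"],
    )


def simulate_ltrc(seed, n=200, p=3, beta=None, trunc_prob=0.3, cens_scale=2.0):
    """Weibull-PH LTRC data for solver tests (continuous times, no ties)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.linspace(0.6, -0.6, p)
    eta = X @ beta
    T = rng.exponential(1.0 / np.exp(eta - eta.mean()))
    U = rng.exponential(cens_scale, n)
    V = np.where(rng.random(n) < trunc_prob, rng.lognormal(-0.5, 0.8, n), 0.0)
    Y = np.minimum(T, U)
    e = (T <= U).astype(int)
    keep = V < Y
    return LTRCDataset(
        entry=V[keep],
        time=Y[keep],
        event=e[keep],
        predictors=X[keep],
        predictor_names=[f"x{i + 1}" for i in range(p)],
    ), np.asarray(beta, dtype=float)


@pytest.fixture
def ltrc_200():
    """Moderate LTRC dataset with ~30% positive entries."""
    ds, beta = simulate_ltrc(7, n=200, p=3)
    return ds, beta
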