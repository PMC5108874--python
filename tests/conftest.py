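import numpy as np
import pytest

from survsvr.survdata import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, d=2, censor_frac=0.4, scale=2.0):
    """Small random right-censored dataset for unit tests."""
    X = rng.standard_normal((n, d))
    y = rng.exponential(scale, n) + 1e-3
    delta = (rng.random(n) > censor_frac).astype(int)
    if delta.sum() == 0:
        delta[int(np.argmin(y))] = 1
    return SurvivalDataset(X, y, delta)


@pytest.fixture
def small_ds(rng):
    return random_survival(rng, 30)


def linear_survival(rng, n, w, noise=0.0, all_events=True, censor_frac=0.3):
    """Dataset whose (latent) survival time is linear in the features."""
    d = len(w)
    X = rng.standard_normal((n, d))
    t = X @ w + 10.0 + noise * rng.standard_normal(n)
    t = np.maximum(t, 1e-2)
    if all_events:
        return SurvivalDataset(X, t, np.ones(n, dtype=int))
    c = rng.exponential(np.median(t) / censor_frac, n)
    y = np.minimum(t, c)
    delta = (t <= c).astype(int)
    if delta.sum() == 0:
        delta[int(np.argmin(y))] = 1
    return SurvivalDataset(X, np.maximum(y, 1e-3), delta)
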