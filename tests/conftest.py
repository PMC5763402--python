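import numpy as np
import pytest

from predmod.trial_data import TrialDataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def _survival(rng, n, beta, X, censor_hi=3.0):
    t = rng.exponential(np.exp(-(X @ beta)))
    c = rng.uniform(0.3, censor_hi, n)
    return np.minimum(t, c), (t <= c).astype(float)


@pytest.fixture()
def small_surv():
    """Small survival problem with a known sparse signal (n=60, p=4)."""
    rng = np.random.default_rng(7)
    n, p = 60, 4
    X = rng.standard_normal((n, p))
    beta = np.array([0.8, 0.0, -0.5, 0.0])
    time, event = _survival(rng, n, beta, X)
    return X, time, event


@pytest.fixture()
def small_dataset():
    """A standardized TrialDataset, n=80, p=6, with one strong modifier."""
    rng = np.random.default_rng(11)
    n, p = 80, 6
    X = rng.standard_normal((n, p))
    T = rng.permutation(np.repeat([0.5, -0.5], n // 2))
    lp = -0.9 * X[:, 2] * T
    t = rng.exponential(np.exp(-lp))
    c = rng.uniform(2, 5, n)
    ds = TrialDataset(X=X, treatment=T, time=np.minimum(t, c),
                      event=(t <= c).astype(float))
    from predmod.trial_data import standardize
    ds, _ = standardize(ds)
    return ds
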