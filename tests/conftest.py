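import numpy as np
import pytest


@pytest.fixture(scope="session")
def small_survival():
    """A 16-row, one-binary-covariate survival dataset with ties."""
    rng = np.random.default_rng(12345)
    n = 16
    x = rng.integers(0, 2, n).astype(float)
    T = rng.exponential(1 / (0.3 * np.exp(0.8 * x)))
    C = rng.uniform(0.5, 6.0, n)
    t = np.round(np.minimum(T, C), 1) + 0.1
    d = (T <= C).astype(int)
    return x, t, d


@pytest.fixture(scope="session")
def sim_survival():
    """A moderate three-covariate dataset for cross-checks."""
    rng = np.random.default_rng(8)
    n = 500
    X = rng.normal(size=(n, 3))
    beta = np.array([0.6, -0.4, 0.0])
    T = rng.exponential(1 / (0.1 * np.exp(X @ beta)))
    C = rng.uniform(0.5, 12, n)
    t = np.minimum(T, C)
    d = (T <= C).astype(int)
    return X, t, d


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-row default-condition synthetic cohort."""
    from aldiet.cohort import default_config, generate_cohort

    cfg = default_config(n_participants=4000, seed=17, baseline_rate=3e-3)
    return generate_cohort(cfg)
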