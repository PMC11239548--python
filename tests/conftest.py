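import numpy as np
import pytest

from cardiohawk import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """200-record cohort (100 healthy) with streams; shared, read-only."""
    spec = sd.CohortSpec(n_total=200, n_healthy=100, seed=7)
    return sd.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def rastrigin(x):
    x = np.asarray(x)
    return float(10 * x.size + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))
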