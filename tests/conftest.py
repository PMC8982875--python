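import numpy as np
import pytest

from oscdecomp import FitConfig, three_oscillator_series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def benchmark_data():
    """One realization of the benchmark 3-oscillator bivariate generator."""
    data, truth = three_oscillator_series(seed=42)
    return data, truth


@pytest.fixture(scope="session")
def fast_fit_config():
    """Single-start fitting configuration used for test-scale studies."""
    return FitConfig(n_starts=1, maxiter=500)
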