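import numpy as np
import pytest

from desperation import ModelParams, StrategyFreqs


@pytest.fixture
def table_params() -> ModelParams:
    """Typical-value parameters (beta=10, pi=20, gamma=1/3, r=0.99)."""
    return ModelParams()


@pytest.fixture
def small_params() -> ModelParams:
    """Cheap parameters for dynamic-programming tests."""
    return ModelParams(grid_n=151, T=20)


@pytest.fixture
def toy_params() -> ModelParams:
    """Tiny instance sized for exhaustive path enumeration."""
    return ModelParams(
        mu=1.0, sigma=2.0, r=0.5, N_pop=10, n_targets=2,
        T=2, grid_lo=-2.0, grid_hi=2.0, grid_n=5,
    )


def random_freqs(rng: np.random.Generator) -> StrategyFreqs:
    e, v, s = rng.dirichlet([1.0, 1.0, 1.0])
    return StrategyFreqs(e=float(e), v=float(v), s=float(s))
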