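import numpy as np
import pandas as pd
import pytest

from hybridgp import Kernel, SimulationScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """Complete single-environment trial small enough for fast fits."""
    return SimulationScenario(
        J=60, p=80, n_env=1, h2_g=0.5, residual_sd=1.0, sparsity=1.0, seed=7
    )


@pytest.fixture
def tiny_markers():
    """4 lines x 5 SNPs with two missing calls."""
    return pd.DataFrame(
        [
            [0, 1, 2, np.nan, 0],
            [1, 0, 2, 1, 0],
            [2, np.nan, 0, 1, 0],
            [0, 1, 1, 2, 0],
        ],
        index=["L0", "L1", "L2", "L3"],
        columns=[f"S{j}" for j in range(5)],
        dtype=float,
    )


def random_psd_kernel(rng, J, name):
    A = rng.normal(size=(J, J + 3))
    K = A @ A.T / (J + 3)
    return Kernel(K, [f"L{i}" for i in range(J)], name)


@pytest.fixture
def standardized_X(rng):
    X = rng.normal(size=(50, 40))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return pd.DataFrame(X, index=[f"L{i:03d}" for i in range(50)])
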