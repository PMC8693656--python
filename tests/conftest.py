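import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from progmark.matrix import normalize_to_log_tpm
from progmark.simulate import SimulationParams, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter simulation (seed 7), normalized, with truth."""
    bulk, sc, truth = simulate_dataset(SimulationParams(seed=7))
    return normalize_to_log_tpm(bulk), normalize_to_log_tpm(sc), truth


@pytest.fixture
def toy_counts():
    """Tiny deterministic count matrix: 4 genes x 3 cells."""
    return pd.DataFrame(
        [[1.0, 0.0, 2.0],
         [3.0, 5.0, 0.0],
         [0.0, 0.0, 0.0],
         [6.0, 5.0, 8.0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["c1", "c2", "c3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
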