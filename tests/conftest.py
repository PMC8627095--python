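import numpy as np
import pandas as pd
import pytest

from mc5 import (
    ExpressionMatrix,
    RunConfig,
    Scale,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Planted two-subtype cohort at the default study conditions (n=200)."""
    return simulate_cohort(SimulationConfig(n_samples=200, seed=11))


@pytest.fixture(scope="session")
def small_cluster_config():
    """Consensus clustering config scaled for test fixtures."""
    return RunConfig(reps=100, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_expr(values, genes=None, samples=None, scale=Scale.LOG2_TPM_PLUS1):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)
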