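import numpy as np
import pandas as pd
import pytest

from pclike import ExpressionMatrix, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One discovery-scale cohort under default study conditions."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for IO/plumbing tests (few genes)."""
    return generate_cohort(
        SimulationConfig(seed=3, n_samples=60, n_genes=40,
                         n_signal_genes=8, n_confounded_genes=8)
    )


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(5)]
    samples = [f"S{j}" for j in range(7)]
    return ExpressionMatrix(genes, samples, rng.normal(5, 2, size=(5, 7)))
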