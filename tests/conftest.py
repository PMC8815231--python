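import numpy as np
import pytest

import colmut as cm


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted survival effects and equal MSS/MSIH rates."""
    config = cm.SimulationConfig(
        n_samples=200, n_genes=60, n_family_genes=10,
        mut_rate_mss=8.0, mut_rate_msih=8.0, seed=11)
    mut, clin, expr, genes, truth = cm.simulate_cohort(config)
    return config, mut, clin, expr, genes, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort under the default study conditions (MSS low / MSIH high burden)."""
    config = cm.SimulationConfig(seed=7)
    return config, *cm.simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
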