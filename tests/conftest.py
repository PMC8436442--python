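import numpy as np
import pytest

import wmconnect as wc


def small_config(seed=0, **overrides):
    """A scaled-down simulation config for fast unit tests: 30 nodes,
    10 + 10 subjects, 3 modules."""
    defaults = dict(
        seed=seed, n_nodes=30, n_controls=10, n_patients=10, n_modules=3,
        nbs_edges=None, pred_edges=None, min_analysis_sparsity=0.30,
    )
    defaults.update(overrides)
    return wc.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return wc.simulate_cohort(small_config(seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (90 nodes, 73 patients / 100 controls)."""
    return wc.simulate_cohort(wc.SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
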