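import numpy as np
import pytest

import ramarkov as rm


@pytest.fixture(scope="session")
def discrete_sim():
    """Mid-size discrete-mode cohort from the published per-visit matrix."""
    cfg = rm.SimulationConfig(n_patients=2000, seed=42, visits_mean=6.0)
    return rm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def discrete_transitions(discrete_sim):
    visits = rm.derive_states(discrete_sim.visits)
    return rm.pair_consecutive_visits(visits)


@pytest.fixture(scope="session")
def ctmc_sim():
    """Mid-size ctmc-mode cohort with published sojourn means as truth."""
    cfg = rm.SimulationConfig(
        n_patients=2000, seed=7, mode="ctmc",
        intensity=rm.reference_intensity(), visits_mean=6.0,
    )
    return rm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ctmc_fit(ctmc_sim):
    visits = rm.derive_states(ctmc_sim.visits)
    trans = rm.pair_consecutive_visits(visits)
    return rm.fit_ctmc(trans)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
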