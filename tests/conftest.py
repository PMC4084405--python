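import numpy as np
import pytest

import swimcpg as s
import swimcpg.cohort as co


@pytest.fixture
def kinetics():
    return s.SynapseKinetics()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    return co.generate_cohort(co.CohortConfig(n_animals=6), seed=7)


@pytest.fixture(scope="session")
def default_animal():
    """An animal pinned at the population-mean synapse amplitudes."""
    from dataclasses import replace

    a = co.generate_cohort(co.CohortConfig(n_animals=2), seed=0)[0]
    return replace(a, h_mv=2.9, d_mv=0.8, epsilon=0.0, zone_zeta=0.0, baseline_bursts=6)
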