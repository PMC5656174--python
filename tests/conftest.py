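import numpy as np
import pytest

from methtriage.simcohort import SimConfig, simulate_consortium

MIXED_FRACTIONS = {
    "null": 0.90,
    "causal": 0.025,
    "cell_mediated_only": 0.025,
    "genetic_confound": 0.025,
    "familial_confound": 0.025,
}

NULL_FRACTIONS = {
    "null": 1.0,
    "causal": 0.0,
    "cell_mediated_only": 0.0,
    "genetic_confound": 0.0,
    "familial_confound": 0.0,
}


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_cohorts=2,
        n_per_cohort=200,
        n_probes=2000,
        seed=7,
        effect_class_fractions=dict(MIXED_FRACTIONS),
        n_discriminating_per_type=8,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_consortium():
    """Two cohorts x 200 trios x 2,000 probes with all effect classes planted."""
    return simulate_consortium(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
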