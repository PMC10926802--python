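import numpy as np
import pytest

from htnsim.config import default_registry
from htnsim.interface import ScenarioSpec, build_analysis_cohort
from htnsim.population import sample_with_replacement


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def values(registry):
    return registry.point_values()


@pytest.fixture(scope="session")
def eligible_cohort(registry):
    """Small weighted analysis cohort shared by engine-level tests."""
    scenario = ScenarioSpec(n_base=3000, n_individuals=400, master_seed=7)
    return build_analysis_cohort(scenario, registry)


@pytest.fixture(scope="session")
def tiny_cohort(eligible_cohort):
    return sample_with_replacement(eligible_cohort, 60, seed=11)
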