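import numpy as np
import pytest

from linevar.simulate import (
    PhenotypeArchitecture,
    SimulationConfig,
    coding_enriched_mixture,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic cohort (L=5, 20k variants): the generator's study conditions."""
    return simulate_cohort(SimulationConfig(seed=12345))


@pytest.fixture(scope="session")
def coding_sim():
    """Selection-shifted cohort with a coding-enriched mixture for category analyses."""
    cfg = SimulationConfig(
        n_variants=10_000,
        category_mixture=coding_enriched_mixture(),
        seed=54321,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny cohort for I/O round trips."""
    return simulate_cohort(SimulationConfig(n_variants=500, n_individuals=20, seed=7))
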