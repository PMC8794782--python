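import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ailqtl import synthetic_data as sd

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ail_cohort():
    """A study-sized AIL cohort: 397 individuals, generation 10, 1000 markers."""
    design = sd.evenly_spaced_design(n_individuals=397, n_generations=10, seed=11)
    return sd.simulate_ail_genotypes(design)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for structural tests."""
    design = sd.evenly_spaced_design(
        n_individuals=60,
        n_generations=10,
        chromosomes=[("1", 100_000_000)],
        markers_per_chromosome=40,
        seed=5,
    )
    return sd.simulate_ail_genotypes(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)
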