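import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from scrrobust import (
    GeneratorConfig,
    allocate_groups,
    bootstrap_dataset,
    generate_null_population,
)


@pytest.fixture(scope="session")
def population():
    """A modest synthetic null population shared across tests."""
    return generate_null_population(GeneratorConfig(n_participants=90, seed=1234))


@pytest.fixture(scope="session")
def labelled_dataset(population):
    """A phase-wise bootstrap of the population with three groups, n=45."""
    rng = np.random.default_rng(99)
    boot = bootstrap_dataset(population, 45, "phase_wise", rng)
    return boot.with_groups(allocate_groups(45, 3, rng))
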