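import numpy as np
import pytest

from ecdsb import (
    SimulationConfig,
    apply_survival,
    generate_untreated_population,
    simulate_population,
)
from ecdsb.survival import PUBLISHED_MT


@pytest.fixture(scope="session")
def untreated_10k():
    return generate_untreated_population(10_000, seed=11)


@pytest.fixture(scope="session")
def untreated_4k():
    return generate_untreated_population(4000, seed=12)


@pytest.fixture(scope="session")
def survivors_by_f(untreated_4k):
    """Bernoulli survivors of the untreated population at the published f values."""
    out = {}
    for i, f in enumerate((770, 170, 40, 30, 3)):
        records = simulate_population(
            untreated_4k, SimulationConfig(binding_frequency=f, seed=100 + i)
        )
        out[f] = apply_survival(
            records, PUBLISHED_MT, "bernoulli", np.random.default_rng(200 + i)
        )
    return out
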