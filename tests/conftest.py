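import numpy as np
import pytest

from epiqtl.simulator import benchmark_design, simulate_family
from epiqtl.structures import LinkageGroup, LinkageMap, QtlPosition


@pytest.fixture(scope="session")
def benchmark_family():
    """One modest benchmark family, shared read-only across tests."""
    return simulate_family(benchmark_design(300, 0.4, seed=42))


@pytest.fixture(scope="session")
def large_family():
    """A large family for frequency/segregation checks."""
    return simulate_family(benchmark_design(20_000, 0.4, seed=7))


@pytest.fixture()
def small_map():
    """A compact two-group map for scan and IO tests."""
    return LinkageMap(
        groups=(
            LinkageGroup("A", ("a1", "a2", "a3"), np.array([0.0, 25.0, 50.0])),
            LinkageGroup("B", ("b1", "b2"), np.array([0.0, 30.0])),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
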