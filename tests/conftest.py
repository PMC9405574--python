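import numpy as np
import pytest

from rssrm.izhikevich import build_behavior_catalog, get_behavior, simulate


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: no order dependence
    return np.random.default_rng(20220729)


@pytest.fixture(scope="session")
def small_catalog():
    """The twenty behaviors at one-tenth duration (fast to simulate)."""
    return build_behavior_catalog(scale=0.1)


@pytest.fixture(scope="session")
def small_traces(small_catalog):
    return {spec.name: simulate(spec) for spec in small_catalog}


@pytest.fixture(scope="session")
def trace_q(small_traces):
    """Shortest behavior: depolarizing after-potential, one spike."""
    return small_traces["q"]


@pytest.fixture(scope="session")
def trace_a(small_traces):
    """Tonic spiking at one-tenth duration (multiple spikes)."""
    return small_traces["a"]
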