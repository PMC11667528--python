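import numpy as np
import pytest

from amypath.markers import MarkerPanel, MarkerSpec
from amypath.simulate import make_tiny_fixture
from amypath.sustain.events import Event, EventSequence


@pytest.fixture(scope="session")
def tiny_fixture():
    """Hard-coded 12-control / 20-case two-marker cohort (N = 2 events)."""
    return make_tiny_fixture()


@pytest.fixture(scope="session")
def panel3():
    """Three single-threshold markers: N = 3 events, 6 valid sequences."""
    return MarkerPanel(
        tuple(
            MarkerSpec(n, "higher_is_worse", z_thresholds=(1.0,), z_max=3.0)
            for n in ("m1", "m2", "m3")
        )
    )


@pytest.fixture(scope="session")
def panel6():
    """Three markers x two thresholds: N = 6 events."""
    return MarkerPanel(
        tuple(
            MarkerSpec(n, "higher_is_worse", z_thresholds=(1.0, 2.0), z_max=5.0)
            for n in ("m1", "m2", "m3")
        )
    )


@pytest.fixture(scope="session")
def seq6_pair(panel6):
    """Two maximally different orderings over panel6."""
    a = EventSequence(
        [Event(0, 0), Event(0, 1), Event(1, 0), Event(1, 1), Event(2, 0), Event(2, 1)],
        panel6,
    )
    b = EventSequence(
        [Event(2, 0), Event(2, 1), Event(1, 0), Event(1, 1), Event(0, 0), Event(0, 1)],
        panel6,
    )
    return a, b


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
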