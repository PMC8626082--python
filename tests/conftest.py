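import numpy as np
import pytest

from zetatest import EventSeries, SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def poisson_train(rng):
    """Stationary 20 Hz Poisson train over 100 s with 2 s event spacing."""
    times = np.sort(rng.uniform(0.0, 100.0, size=2000))
    return SpikeTrain(times, "poisson-20hz")


@pytest.fixture
def regular_events():
    return EventSeries(np.arange(0.0, 100.0, 2.0))
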