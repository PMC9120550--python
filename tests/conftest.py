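import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pyzapline import run
from pyzapline.core import Recording
from pyzapline.synthetic import standard_fixture

settings.register_profile(
    "suite",
    max_examples=30,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


def _truth(name):
    return standard_fixture(name, seed=0)


@pytest.fixture(scope="session")
def stationary_truth():
    return _truth("stationary-50Hz")


@pytest.fixture(scope="session")
def drifting_truth():
    return _truth("drifting-peak")


@pytest.fixture(scope="session")
def switching_truth():
    return _truth("switching-topography")


@pytest.fixture(scope="session")
def twofreq_truth():
    return _truth("two-frequency")


@pytest.fixture(scope="session")
def megstrong_truth():
    return _truth("meg-strong")


@pytest.fixture(scope="session")
def clean_truth():
    return _truth("clean-only")


@pytest.fixture(scope="session")
def stationary_run(stationary_truth):
    return run(stationary_truth.combined)


@pytest.fixture(scope="session")
def drifting_run(drifting_truth):
    return run(drifting_truth.combined)


@pytest.fixture(scope="session")
def switching_run(switching_truth):
    return run(switching_truth.combined)


@pytest.fixture(scope="session")
def twofreq_run(twofreq_truth):
    return run(twofreq_truth.combined)


@pytest.fixture(scope="session")
def megstrong_run(megstrong_truth):
    return run(megstrong_truth.combined)


@pytest.fixture(scope="session")
def small_recording():
    """A short, cheap recording with a planted 50 Hz artifact for I/O tests."""
    rng = np.random.default_rng(7)
    n_ch, srate, dur = 6, 250.0, 60.0
    n = int(srate * dur)
    t = np.arange(n) / srate
    topo = rng.standard_normal(n_ch)
    data = rng.standard_normal((n_ch, n)) + 2.0 * np.outer(
        topo, np.sin(2 * np.pi * 50.0 * t)
    )
    return Recording(data, srate, [f"ch{i}" for i in range(n_ch)])
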