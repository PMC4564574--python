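import numpy as np
import pytest

from pupilcc.pipeline import RunConfig
from pupilcc.preprocess import MonoTrace
from pupilcc.synth import DesignConfig, SimConfig, simulate_subject

RATE = 60.0
DT = 1000.0 / RATE


def make_trace(diameters, missing=None, rate_hz=RATE, t0=0.0):
    """Uniform-grid MonoTrace from a value list; NaN entries mark missing."""
    d = np.asarray(diameters, dtype=float)
    if missing is None:
        missing = np.isnan(d)
    return MonoTrace(
        time_ms=t0 + np.arange(d.size) * (1000.0 / rate_hz),
        diameter_mm=d,
        missing=np.asarray(missing, dtype=bool),
        rate_hz=rate_hz,
    )


@pytest.fixture(scope="session")
def design():
    return DesignConfig()


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_subject(design):
    """One fully simulated subject (all three tasks), shared across tests."""
    sim = SimConfig(seed=42, n_subjects=1)
    return sim, simulate_subject(design, sim, 0)
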