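import numpy as np
import pytest
from hypothesis import settings

from kmburst.model import ModelParams, Modulation, SimConfig, simulate

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def burst_traces():
    """The three burst scenarios (baseline, g_M x2, both x2) at the
    production step size; shared across burst/model/acceptance tests."""
    cfg = SimConfig(duration_ms=3000.0, dt_ms=0.001, equilibration_ms=1000.0)
    mods = {"base": Modulation(1.0, 1.0), "gm2": Modulation(2.0, 1.0),
            "both2": Modulation(2.0, 2.0)}
    return {k: simulate(ModelParams(), cfg, m) for k, m in mods.items()}


@pytest.fixture(scope="session")
def long_traces():
    """Longer runs (several burst cycles) for trajectory-loop analysis."""
    cfg = SimConfig(duration_ms=7000.0, dt_ms=0.002, equilibration_ms=1000.0)
    mods = {"base": Modulation(1.0, 1.0), "gm2": Modulation(2.0, 1.0),
            "both2": Modulation(2.0, 2.0)}
    return {k: simulate(ModelParams(), cfg, m) for k, m in mods.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
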