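import pytest

from evlpsim.parameters import default_config
from evlpsim.simulator import SolverSettings, run_to_steady_state


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def fast_settings():
    """Looser tolerance for tests that exercise behaviour, not accuracy."""
    return SolverSettings(rtol=1e-7, atol=1e-7)


@pytest.fixture(scope="session")
def default_steady(config):
    """Converged steady state and cycle-mean outputs at default parameters."""
    return run_to_steady_state(config)


@pytest.fixture(scope="session")
def default_steady_fast(config, fast_settings):
    return run_to_steady_state(config, settings=fast_settings)
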