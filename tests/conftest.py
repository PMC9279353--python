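import pytest
from hypothesis import HealthCheck, settings

from guvflux.calibration import BufferSystem, CalibrationCurve
from guvflux.simulate import SimulationConfig, simulate_acidification

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def buffer():
    """10 mM HEPES at 21 degC — the assay buffer."""
    return BufferSystem.hepes()


@pytest.fixture(scope="session")
def curve():
    return CalibrationCurve()


@pytest.fixture(scope="session")
def strong_config():
    """Default strong-acid (HCl) scenario."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def strong_trace(strong_config):
    """Unclamped strong-acid run at default study conditions."""
    return simulate_acidification(strong_config)


@pytest.fixture(scope="session")
def clamped_config(strong_config):
    from dataclasses import replace

    return replace(strong_config, clamp_potential=True)


@pytest.fixture(scope="session")
def clamped_trace(clamped_config):
    """Potential-clamped (Fick-mode) twin of the strong-acid run."""
    return simulate_acidification(clamped_config)
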