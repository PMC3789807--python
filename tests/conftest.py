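import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from focalheat import LaserProtocol, Medium, SourceModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water() -> Medium:
    return Medium.water()


@pytest.fixture(scope="session")
def spheroid_source() -> SourceModel:
    return SourceModel()


@pytest.fixture(scope="session")
def isotropic_source() -> SourceModel:
    return SourceModel(lateral_radius_um=1.0, axial_radius_um=1.0)


@pytest.fixture(scope="session")
def khz_protocol() -> LaserProtocol:
    """1 kHz repetition, 0.2 ms pulses — the phase-gated measurement timing."""
    return LaserProtocol(
        mode="pulsed", repetition_frequency_hz=1000.0, pulse_length_ms=0.2
    )


@pytest.fixture(scope="session")
def cw_protocol() -> LaserProtocol:
    return LaserProtocol(
        mode="cw", repetition_frequency_hz=None, pulse_length_ms=None,
        incident_power_mw=150.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
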