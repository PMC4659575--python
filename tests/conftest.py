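import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from atriomech.myofilament import RiceParameters
from atriomech.cell import PacingProtocol, run_pacing


@pytest.fixture(scope="session")
def rice():
    return RiceParameters()


@pytest.fixture(scope="session")
def steady_protocol():
    """The full 1 Hz S1 protocol (1000 beats) used for reported biomarkers."""
    return PacingProtocol(s1_count=1000)


@pytest.fixture(scope="session")
def ra_control(steady_protocol):
    return run_pacing("RA/PM", "control", steady_protocol)


@pytest.fixture(scope="session")
def ra_af(steady_protocol):
    return run_pacing("RA/PM", "af", steady_protocol)


@pytest.fixture(scope="session")
def short_protocol():
    """Short conditioning train for kinetics-level tests (drift documented
    in the methods note; steady-state values use the 1000-beat protocol)."""
    return PacingProtocol(s1_count=50)
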