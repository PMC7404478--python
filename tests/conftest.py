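import warnings

import numpy as np
import pytest

from stridepower.simulate import (
    DeviceBiasModel,
    GaitModel,
    ProtocolConfig,
    SubjectProfile,
    simulate_session,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def subject() -> SubjectProfile:
    return SubjectProfile(mass=70.0, height=1.75, initial_speed_kmh=10.0)


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolConfig:
    """Five-stage protocol: enough laps for every downstream stage."""
    return ProtocolConfig(max_speed_kmh=12.0)


@pytest.fixture(scope="session")
def noiseless_session(subject, short_protocol):
    """Bias-free, noise-free session: device truth equals ground truth."""
    return simulate_session(subject, short_protocol, DeviceBiasModel(), seed=11)


@pytest.fixture(scope="session")
def biased_session(subject, short_protocol):
    """Session with the device bias regime under study (-300 W and worse
    with speed, plus channel noise)."""
    return simulate_session(
        subject, short_protocol, DeviceBiasModel.underreading(), seed=11
    )
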