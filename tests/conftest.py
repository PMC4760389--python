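import numpy as np
import pytest

from cmcoherence import (
    DriveModelParams,
    ProtocolParams,
    generate_session,
)

FS = 2048.0


@pytest.fixture(scope="session")
def default_drive():
    return DriveModelParams(seed=42)


@pytest.fixture(scope="session")
def default_protocol():
    return ProtocolParams()


@pytest.fixture(scope="session")
def short_protocol():
    """One block of 10 trials: same trial structure, quick to generate."""
    return ProtocolParams(n_blocks=1, trials_per_block=10)


@pytest.fixture(scope="session")
def default_session(default_drive, default_protocol):
    """Full 150-trial session at study conditions (generated once)."""
    return generate_session(default_drive, default_protocol, "S01", "pre")


@pytest.fixture(scope="session")
def short_session(default_drive, short_protocol):
    return generate_session(default_drive, short_protocol, "S01", "pre")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
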