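import numpy as np
import pytest

from octquant.oct import SystemConfig


@pytest.fixture
def system() -> SystemConfig:
    """Default imaging geometry with roll-off disabled."""
    return SystemConfig(rolloff_decay=None)


@pytest.fixture
def system_rolloff() -> SystemConfig:
    return SystemConfig(rolloff_decay=800.0)


@pytest.fixture
def z_grid() -> np.ndarray:
    """600 um of depth at the nominal 2.9 um axial pitch."""
    return np.arange(207) * 2.9
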