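import numpy as np
import pytest

from spirobench.device_model import default_calibration
from spirobench.simulate import SessionScript, make_session


@pytest.fixture(scope="session")
def cal():
    return default_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def asthma_session(cal):
    """One noisy asthma session (trace + ground truth), shared read-only."""
    script = SessionScript(subject_group="asthma", rng_seed=42)
    return make_session(script, cal=cal)


@pytest.fixture(scope="session")
def clean_session(cal):
    """Noise-free, ADC-bypassed control session for exact pipeline checks."""
    script = SessionScript(subject_group="control", rng_seed=7)
    return make_session(script, cal=cal, noisy=False, quantize=False)
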