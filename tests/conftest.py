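import numpy as np
import pytest

from ripplelab.synth import IedConfig, SwrConfig, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def mixed_recording():
    """60 s single-electrode recording carrying both SWRs and IEDs."""
    return generate_recording(SynthConfig(duration=60.0, seed=1))


@pytest.fixture(scope="session")
def swr_recording():
    """60 s SWR-only recording (physiological condition)."""
    return generate_recording(SynthConfig(duration=60.0, seed=3,
                                          ied=IedConfig(rate=0.0)))


@pytest.fixture(scope="session")
def ied_recording():
    """60 s IED-only recording (epileptiform condition)."""
    return generate_recording(SynthConfig(duration=60.0, seed=4,
                                          swr=SwrConfig(rate=0.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
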