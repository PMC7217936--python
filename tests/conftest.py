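import numpy as np
import pytest

from phasermt.containers import Recording
from phasermt.realtime import RtConfig
from phasermt.synth import MuSourceParams, generate_recording

LAPLACIAN_SET = ("C3", "FC1", "FC5", "CP1", "CP5")


@pytest.fixture(scope="session")
def noiseless_recording() -> Recording:
    """Pure 10-Hz mu on the C3 Laplacian set, no noise, no envelope."""
    params = MuSourceParams(mu_freq=10.0, mu_amp=2.0, noise_scale=0.0,
                            mod_depth=0.0)
    return generate_recording(params, duration=20.0, seed=1,
                              channels=LAPLACIAN_SET)


@pytest.fixture(scope="session")
def snr5_recording() -> Recording:
    """Mu at the 5-dB inclusion-floor SNR in 1/f noise."""
    params = MuSourceParams(mu_freq=10.0, target_snr_db=5.0)
    return generate_recording(params, duration=70.0, seed=7,
                              channels=LAPLACIAN_SET)


@pytest.fixture
def rt_config() -> RtConfig:
    return RtConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
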