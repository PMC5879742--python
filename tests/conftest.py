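import numpy as np
import pytest

from texelec.bench import ECGSynthSpec, synth_ecg
from texelec.cole import ColeParameters

# parameters of the reference single-dispersion contact-impedance model for
# PEDOT:PSS-treated textile electrodes
FIG_R_INF = 35065.0  # ohm
FIG_R1 = 3.701e6  # ohm
FIG_C1 = 15.129e-9  # farad
FIG_ALPHA1 = 0.8397


@pytest.fixture(scope="session")
def textile_cole() -> ColeParameters:
    return ColeParameters.single(FIG_R_INF, FIG_R1, FIG_C1, FIG_ALPHA1)


@pytest.fixture(scope="session")
def sweep_grid() -> np.ndarray:
    """51 log-spaced frequencies, 0.1 Hz-10 kHz (10 points/decade)."""
    return np.logspace(np.log10(0.1), np.log10(1.0e4), 51)


@pytest.fixture(scope="session")
def clean_ecg():
    """60 s of clean 60 bpm synthetic ECG with light white noise."""
    return synth_ecg(ECGSynthSpec(duration=60.0, heart_rate=60.0, white_noise_sd=0.01, seed=7))
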