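import warnings

import numpy as np
import pytest

from cvep.codes import generate_chaotic_code, generate_m_sequence, make_stimulus_set
from cvep.preproc import preprocess_study
from cvep.synthdata import SimulationConfig, make_vep_kernel, simulate_study


@pytest.fixture(scope="session")
def chaotic_code():
    return generate_chaotic_code()


@pytest.fixture(scope="session")
def mseq_code():
    return generate_m_sequence()


@pytest.fixture(scope="session")
def chaotic_set(chaotic_code):
    return make_stimulus_set(chaotic_code)


@pytest.fixture(scope="session")
def sim_study(chaotic_set):
    """One simulated chaotic-code study at the default -5 dB, preprocessed.

    fs = 540 Hz (an integer multiple of the 90 Hz code rate) so epoch
    boundaries are sample-exact; shared across decoder tests.
    """
    fs = 540.0
    kernel = make_vep_kernel(fs_hz=fs, seed=7)
    cfg = SimulationConfig(fs_hz=fs, seed=42)
    recs = simulate_study(chaotic_set, kernel, cfg)
    return preprocess_study(recs)


@pytest.fixture(scope="session")
def noiseless_study(chaotic_set):
    """Noise-free simulated study (unfiltered) for exact-structure checks."""
    fs = 540.0
    kernel = make_vep_kernel(fs_hz=fs, seed=7)
    cfg = SimulationConfig(fs_hz=fs, snr_db=np.inf, seed=0)
    recs = simulate_study(chaotic_set, kernel, cfg)
    return preprocess_study(recs, filter_data=False)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*not an integer multiple of the code rate.*"
        )
        warnings.filterwarnings("ignore", message=".*training epochs for a .*-dimensional covariance.*")
        yield
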