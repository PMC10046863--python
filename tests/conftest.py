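import numpy as np
import pytest

import cmtfusion as cf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def basis_k2():
    return cf.build_hrf_basis(K=2, TR=2.0, duration=32.0)


@pytest.fixture(scope="session")
def basis_k3():
    return cf.build_hrf_basis(K=3, TR=2.0, duration=32.0)


@pytest.fixture(scope="session")
def small_stim():
    """10-trial paradigm -> 70 volumes at TR = 2 s."""
    return cf.generate_stimulus_timecourse(n_trials=10, TR=2.0,
                                           condition="both", seed=1)


@pytest.fixture(scope="session")
def small_truth(small_stim):
    return cf.generate_ground_truth(
        R=2, K=2, Q=1, dims=(70, 10, 8, 15), stimulus=small_stim, seed=3
    )


@pytest.fixture(scope="session")
def small_coupled(small_truth, basis_k2):
    """Noisy coupled data from the small ground truth (SNR 20 dB)."""
    X = cf.assemble_eeg_tensor(small_truth, snr_db=20.0, seed=4)
    Y = cf.assemble_fmri_matrix(small_truth, basis_k2, snr_db=20.0, seed=5)
    return X, Y
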