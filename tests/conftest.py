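import numpy as np
import pytest

from mitransfer.io import TrialTensor
from mitransfer.model import EEGNetConfig
from mitransfer.synth import SynthConfig, make_subject_trials


@pytest.fixture(scope="session")
def tiny_model_cfg() -> EEGNetConfig:
    """A miniature architecture for gradient/shape checks."""
    return EEGNetConfig(n_channels=6, n_samples=64, f1=2, depth=2, f2=4,
                        temporal_kernel=8, separable_kernel=5,
                        pool1=4, pool2=4, dropout_p=0.5)


@pytest.fixture(scope="session")
def fast_synth_cfg() -> SynthConfig:
    """Small, quick-to-generate subject: 8 channels, 200 Hz, 20 trials."""
    return SynthConfig(n_channels=8, fs=200.0, trial_len_s=1.5, n_trials=20,
                       rest_s=0.5, gap_s=0.25, seed=321)


@pytest.fixture(scope="session")
def fast_trials(fast_synth_cfg) -> TrialTensor:
    """Preprocessed, separable trials for training-loop tests (T=150)."""
    return make_subject_trials(fast_synth_cfg, target_fs=100.0)


@pytest.fixture(scope="session")
def fast_model_cfg(fast_trials) -> EEGNetConfig:
    return EEGNetConfig(n_channels=fast_trials.n_channels,
                        n_samples=fast_trials.n_samples)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
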