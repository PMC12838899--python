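import numpy as np
import pytest

from seizewin.bilstm_model import ModelConfig, train_model
from seizewin.featurize import FrameConfig, featurize_recording
from seizewin.synth_eeg import SynthConfig, generate_cohort, generate_recording


@pytest.fixture(scope="session")
def frame_cfg():
    return FrameConfig()


@pytest.fixture(scope="session")
def small_synth_cfg():
    """Desk-scale cohort: short recordings, short seizures, strong signal."""
    return SynthConfig(
        n_patients=3,
        seizures_per_patient=(2, 3),
        recording_duration_s=500.0,
        seizure_duration_s=(6.0, 40.0),
        duration_mean_s=18.0,
        interictal_gap_s=60.0,
        seizure_gain=4.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_synth_cfg):
    return generate_cohort(small_synth_cfg)


@pytest.fixture(scope="session")
def single_recording(small_synth_cfg):
    rec, anns = generate_recording(small_synth_cfg, "pX", seed=7)
    return rec, anns


@pytest.fixture(scope="session")
def balanced_packets(single_recording, frame_cfg):
    rec, anns = single_recording
    return featurize_recording(rec, anns, frame_cfg, balance=True, seed=0)


@pytest.fixture(scope="session")
def window_model(balanced_packets):
    """A quick window-granularity model trained on one recording."""
    cfg = ModelConfig(
        hidden_sizes=(16,), learning_rate=0.01, epochs=4,
        granularity="window", seed=0,
    )
    return train_model(balanced_packets, cfg)


@pytest.fixture(scope="session")
def sample_model(balanced_packets):
    """A tiny sample-granularity model (slow path, kept minimal)."""
    cfg = ModelConfig(
        hidden_sizes=(8,), learning_rate=0.01, epochs=2,
        granularity="sample", seed=0,
    )
    return train_model(balanced_packets, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
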