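"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

import conscidet as cd


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest useful paradigm: both cohort modes, a handful of stimuli."""
    return cd.ParadigmConfig(modes=("active", "breathing"), blocks_per_mode=1,
                             n_standard=8, n_deviant=4, n_correct_novel=2,
                             n_incorrect_novel=2, sampling_rate_hz=250.0)


@pytest.fixture(scope="session")
def conscious_epochs():
    """Preprocessed epochs of one scaled conscious subject (cached)."""
    rec = cd.simulate_subject(cd.cohort_config(), cd.conscious_profile(),
                              seed=7)
    return cd.preprocess_recording(rec)


@pytest.fixture(scope="session")
def unconscious_epochs():
    rec = cd.simulate_subject(cd.cohort_config(), cd.unconscious_profile(),
                              seed=8)
    return cd.preprocess_recording(rec)


def make_epochs(data, fs=250.0, channel_names=None, labels=None):
    """Build an EpochSet around a raw (trials, channels, times) array."""
    import pandas as pd

    n_tr, n_ch, n_t = data.shape
    channel_names = channel_names or cd.MONTAGE_32[:n_ch]
    times = (np.arange(n_t) - int(round(0.2 * fs))) * 1000.0 / fs
    if labels is None:
        labels = pd.DataFrame({
            "event_index": np.arange(n_tr), "onset_ms": np.arange(n_tr) * 1500.0,
            "stimulus_type": ["deviant"] * n_tr, "mode": ["active"] * n_tr,
            "block": 0, "modality": "visual"})
    return cd.EpochSet(data, channel_names, fs, times, labels)
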