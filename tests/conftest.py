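import numpy as np
import pytest

import dualeeg as dg


@pytest.fixture(scope="session")
def small_cohort():
    """6-channel, 250 Hz, 50-s cohort of 3+3 subjects with a strong effect."""
    cfg = dg.CohortConfig(n_subjects_per_group=(3, 3), n_channels=6,
                          fs=250.0, duration_seconds=50.0, seed=7)
    params_sz, params_hc = dg.strong_effect()
    return dg.generate_cohort(params_sz, params_hc, cfg), cfg


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    recordings, _cfg = small_cohort
    return dg.build_dataset(recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_window(data, fs=250.0, normalized=True, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels or tuple(f"C{i}" for i in range(data.shape[0]))
    return dg.EEGWindow(data=data, fs=fs, channel_labels=labels,
                        subject_id="t", window_index=0, label="control",
                        normalized=normalized)
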