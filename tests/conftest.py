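import dataclasses

import numpy as np
import pandas as pd
import pytest

from iednet.io import Recording
from iednet.synth import IEDWaveform, patient_bundle, small_config


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort configuration shared across tests."""
    return small_config(seed=3)


@pytest.fixture(scope="session")
def patient0(small_cfg):
    return patient_bundle(small_cfg, 0)


@pytest.fixture(scope="session")
def background_cfg():
    """Pure 1/f background: no couplings, no transient, no local noise."""
    return dataclasses.replace(
        small_config(seed=5), coupling_spec=(), sync_spec=(),
        ied_waveform=IEDWaveform(spike_amplitude=0.0, slow_wave_amplitude=0.0),
        local_noise_sd=0.0, reference_sd=0.0)


def make_recording(data, fs=200.0, modality="scalp", labels=None, **cols):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"c{i}" for i in range(data.shape[0])]
    table = pd.DataFrame({"label": labels, "modality": modality, **cols})
    return Recording(data, fs, table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
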