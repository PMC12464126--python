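import numpy as np
import pytest

from bandstates.synthetic import (StateSequenceParams, make_template_maps,
                                  simulate_state_sequence, synthesize_eeg)


@pytest.fixture(scope="session")
def templates6():
    """Six planted dipolar template maps on the 64-channel montage."""
    return make_template_maps(6, 64, seed=1)


@pytest.fixture(scope="session")
def planted_recording(templates6):
    """One theta-band recording with known labels at SNR 5 (60 s, 128 Hz)."""
    params = StateSequenceParams(
        mean_duration_ms=np.full(6, 80.0), weights=np.ones(6),
        fs=128.0, total_duration_s=60.0, seed=42)
    labels = simulate_state_sequence(params)
    rec = synthesize_eeg(templates6, labels, band="theta", snr=5.0,
                         fs=128.0, seed=43)
    return rec, labels


@pytest.fixture(scope="session")
def clean_recording(templates6):
    """Near-noiseless theta recording with known labels (30 s)."""
    params = StateSequenceParams(
        mean_duration_ms=np.full(6, 80.0), weights=np.ones(6),
        fs=128.0, total_duration_s=30.0, seed=7)
    labels = simulate_state_sequence(params)
    rec = synthesize_eeg(templates6, labels, band="theta", snr=1e12,
                         fs=128.0, seed=8)
    return rec, labels
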