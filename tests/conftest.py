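import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ecgsqa import ECGSignal
from ecgsqa.synthetic import SynthConfig, generate_ecg


@pytest.fixture(scope="session")
def clean_normal():
    """Noise-free normal-morphology recording with ground truth (60 s, 72 bpm)."""
    cfg = SynthConfig(morphology="normal", hr_bpm=72, duration_s=60, fs=1000, seed=9)
    sig, truth = generate_ecg(cfg)
    return cfg, sig, truth


@pytest.fixture(scope="session")
def clean_large_t():
    """Noise-free large-T recording: T amplitude 1.2x the R amplitude."""
    cfg = SynthConfig(morphology="large_t", hr_bpm=60, duration_s=62, fs=500, seed=11)
    sig, truth = generate_ecg(cfg)
    return cfg, sig, truth


def gaussian_pulse(sigma_s: float, fs: float, amplitude: float = 1.0,
                   pad_s: float = 0.5) -> ECGSignal:
    """Isolated Gaussian pulse centered in a zero-baseline record.

    Compactly supported: samples beyond 5 sigma are exactly zero, like the
    beats the synthetic generator places."""
    t = np.arange(-pad_s, pad_s, 1.0 / fs)
    v = amplitude * np.exp(-0.5 * (t / sigma_s) ** 2)
    v[np.abs(t) > 5 * sigma_s] = 0.0
    return ECGSignal(v, fs)
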