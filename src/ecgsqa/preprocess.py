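"""Denoising: Savitzky-Golay smoothing, powerline notch, baseline correction.

All three operations preserve length and sampling rate and use mirror
padding at the edges. The baseline (0-point) estimator is a two-stage
median filter: a short window (~QRS length) flattens the sharp complexes,
a longer window then tracks only the slow drift, which is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .core import ECGSignal

__all__ = [
    "PreprocessParams",
    "savgol_smooth",
    "remove_powerline",
    "correct_baseline",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Denoising parameters.

    ``savgol_window_s`` (default 25 ms) is short enough to preserve the R
    apex while suppressing high-frequency noise; ``baseline_window_s``
    (default 0.6 s) must exceed one QRS complex so the slow-trend estimate
    ignores the beats themselves.
    """

    savgol_window_s: float = 0.025
    savgol_order: int = 3
    mains_freq: float = 50.0
    notch_q: float = 30.0
    baseline_window_s: float = 0.6

    def __post_init__(self) -> None:
        if self.savgol_window_s <= 0 or self.baseline_window_s <= 0:
            raise ValueError("filter windows must be positive")
        if self.savgol_order < 1:
            raise ValueError("savgol_order must be >= 1")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")


def _odd_window(window_s: float, fs: float, minimum: int = 3) -> int:
    w = max(minimum, int(round(window_s * fs)))
    return w if w % 2 == 1 else w + 1


def savgol_smooth(sig: ECGSignal, params: PreprocessParams | None = None) -> ECGSignal:
    """Least-squares local-polynomial (Savitzky-Golay) smoothing."""
    params = params or PreprocessParams()
    window = _odd_window(params.savgol_window_s, sig.fs)
    if window <= params.savgol_order:
        raise ValueError(
            f"Savitzky-Golay window ({window} samples) must exceed the "
            f"polynomial order ({params.savgol_order})"
        )
    if window >= sig.n_samples:
        raise ValueError("Savitzky-Golay window must be shorter than the record")
    out = sps.savgol_filter(
        sig.samples, window_length=window, polyorder=params.savgol_order, mode="mirror"
    )
    return sig.replace_samples(out)


def remove_powerline(sig: ECGSignal, params: PreprocessParams | None = None) -> ECGSignal:
    """Zero-phase IIR notch at the mains frequency (>= 40 dB at the notch)."""
    params = params or PreprocessParams()
    nyq = sig.fs / 2.0
    if params.mains_freq >= nyq:
        raise ValueError(
            f"mains frequency {params.mains_freq} Hz is at or above Nyquist ({nyq} Hz)"
        )
    b, a = sps.iirnotch(params.mains_freq, Q=params.notch_q, fs=sig.fs)
    out = sps.filtfilt(b, a, sig.samples, padtype="even")
    return sig.replace_samples(out)


def correct_baseline(
    sig: ECGSignal, params: PreprocessParams | None = None
) -> tuple[ECGSignal, np.ndarray]:
    """Estimate and subtract the slow baseline trend.

    Returns the corrected signal and the baseline estimate (same length,
    for plotting/inspection). The corrected trace has median ~0.
    """
    params = params or PreprocessParams()
    if params.baseline_window_s >= sig.duration:
        raise ValueError("baseline window must be shorter than the record")
    short = _odd_window(params.baseline_window_s / 3.0, sig.fs)
    long = _odd_window(params.baseline_window_s, sig.fs)
    stage1 = ndimage.median_filter(sig.samples, size=short, mode="reflect")
    baseline = ndimage.median_filter(stage1, size=long, mode="reflect")
    corrected = sig.samples - baseline
    # pin the 0-point: fold any residual median into the baseline estimate
    med = float(np.median(corrected))
    baseline = baseline + med
    corrected = corrected - med
    return sig.replace_samples(corrected), baseline


def preprocess(
    sig: ECGSignal, params: PreprocessParams | None = None
) -> ECGSignal:
    """Full chain: smoothing, notch, baseline correction."""
    params = params or PreprocessParams()
    out = savgol_smooth(sig, params)
    out = remove_powerline(out, params)
    out, _ = correct_baseline(out, params)
    return out
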