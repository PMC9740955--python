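"""R/S/T fiducial detection and per-recording feature extraction.

R candidates are local maxima exceeding a fixed fraction (default 60%) of
the record's global positive extremum, thinned by a refractory period.
The S wave is the minimum in a short window after each R, the T wave the
maximum in a later window. All detection assumes a baseline-corrected
trace whose 0-point sits at 0 V.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import ECGSignal, FeatureSet, WaveAnnotation

__all__ = [
    "DetectionParams",
    "detect_r_peaks",
    "detect_s_wave",
    "detect_t_wave",
    "rr_intervals",
    "compute_features",
    "relative_peak_amplitude",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds and physiological search windows.

    ``threshold_fraction`` is referenced to the global positive extremum of
    the record (one horizontal threshold line for the whole trace). The S
    search runs up to ``s_search_s`` after each R; the T search spans
    ``t_search_s`` (a [lower, upper] pair) after each R.
    """

    threshold_fraction: float = 0.6
    refractory_s: float = 0.200
    s_search_s: float = 0.08
    t_search_s: tuple[float, float] = (0.12, 0.45)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.refractory_s <= 0 or self.s_search_s <= 0:
            raise ValueError("refractory_s and s_search_s must be positive")
        lo, hi = self.t_search_s
        if not (0 < lo < hi):
            raise ValueError("t_search_s must be an increasing positive pair")


def detect_r_peaks(
    sig: ECGSignal, params: DetectionParams | None = None
) -> list[WaveAnnotation]:
    """Find R-wave *candidates*: local maxima above the amplitude threshold.

    Candidates closer together than the refractory period are thinned,
    keeping the larger (ties: the earlier sample). A flat or all-zero
    record yields an empty list. Large T waves that clear the threshold are
    returned as candidates too — separating them from true R waves is the
    discriminator's job.
    """
    params = params or DetectionParams()
    v = sig.samples
    vmax = float(v.max())
    if vmax <= 0:
        return []
    threshold = params.threshold_fraction * vmax
    peaks, _ = sps.find_peaks(v, height=threshold)
    if peaks.size == 0:
        return []
    # refractory thinning: visit by descending amplitude, earlier index wins ties
    order = sorted(range(peaks.size), key=lambda i: (-v[peaks[i]], peaks[i]))
    min_gap = params.refractory_s * sig.fs
    kept: list[int] = []
    for i in order:
        p = peaks[i]
        if all(abs(p - q) >= min_gap for q in kept):
            kept.append(p)
    kept.sort()
    return [
        WaveAnnotation(
            wave="R",
            sample_index=int(p),
            time_s=sig.start_time + p / sig.fs,
            amplitude=float(v[p]),
        )
        for p in kept
    ]


def detect_s_wave(
    sig: ECGSignal, r: WaveAnnotation, params: DetectionParams | None = None
) -> Optional[WaveAnnotation]:
    """Minimum of the trace within ``s_search_s`` after the R peak.

    Returns ``None`` when the search window runs past the record end or no
    sample dips below the baseline.
    """
    params = params or DetectionParams()
    start = r.sample_index + 1
    stop = r.sample_index + int(round(params.s_search_s * sig.fs)) + 1
    if stop > sig.n_samples:
        return None
    window = sig.samples[start:stop]
    i = int(np.argmin(window))
    if window[i] >= 0:
        return None
    idx = start + i
    return WaveAnnotation(
        wave="S",
        sample_index=idx,
        time_s=sig.start_time + idx / sig.fs,
        amplitude=float(window[i]),
    )


def detect_t_wave(
    sig: ECGSignal,
    r: WaveAnnotation,
    params: DetectionParams | None = None,
    next_r: Optional[WaveAnnotation] = None,
) -> Optional[WaveAnnotation]:
    """Maximum of the trace within the T search window after the R peak.

    The window is truncated at the next R minus the refractory period when
    beats are close. Returns ``None`` when the window runs past the record
    end or no sample rises above the baseline.
    """
    params = params or DetectionParams()
    lo, hi = params.t_search_s
    start = r.sample_index + int(round(lo * sig.fs))
    stop = r.sample_index + int(round(hi * sig.fs)) + 1
    if next_r is not None:
        stop = min(stop, next_r.sample_index - int(round(params.refractory_s * sig.fs)))
    if stop > sig.n_samples:
        return None
    if stop <= start:
        return None
    window = sig.samples[start:stop]
    i = int(np.argmax(window))
    if window[i] <= 0:
        return None
    idx = start + i
    return WaveAnnotation(
        wave="T",
        sample_index=idx,
        time_s=sig.start_time + idx / sig.fs,
        amplitude=float(window[i]),
    )


def rr_intervals(r_peaks: Sequence[WaveAnnotation]) -> list[float]:
    """Successive R-to-R time differences in seconds."""
    if len(r_peaks) < 2:
        return []
    times = [r.time_s for r in r_peaks]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("R annotations must be sorted by time")
    return [b - a for a, b in zip(times, times[1:])]


def compute_features(
    annotations: Sequence[WaveAnnotation],
    rr: Sequence[float] | None = None,
) -> FeatureSet:
    """Per-recording features: median wave amplitudes and RR statistics.

    S amplitude is reported as a magnitude. RR-derived fields are ``None``
    with fewer than two beats. ``rr`` defaults to the successive
    differences of the R annotations present in ``annotations``.
    """
    anns = sorted(annotations, key=lambda a: a.sample_index)
    by_wave: dict[str, list[float]] = {"R": [], "S": [], "T": []}
    for a in anns:
        by_wave[a.wave].append(a.amplitude)
    if rr is None:
        rr = rr_intervals([a for a in anns if a.wave == "R"])

    beat_count = len(by_wave["R"])
    a_r = float(np.median(by_wave["R"])) if by_wave["R"] else None
    a_t = float(np.median(by_wave["T"])) if by_wave["T"] else None
    a_s = float(np.median(np.abs(by_wave["S"]))) if by_wave["S"] else None
    if len(rr) >= 1 and beat_count >= 2:
        t_rrint = float(np.median(rr))
        r_maxmin = float(np.max(rr) / np.min(rr))
        hr = 60.0 / t_rrint
    else:
        t_rrint = r_maxmin = hr = None
    return FeatureSet(
        a_rwave=a_r,
        a_twave=a_t,
        a_swave=a_s,
        t_rrint=t_rrint,
        r_rrint_maxmin=r_maxmin,
        beat_count=beat_count,
        hr_bpm=hr,
    )


def relative_peak_amplitude(per_log_amplitudes: Sequence[float]) -> float:
    """Spread of a wave's amplitude across repeated logs: (max-min)/max.

    Input is one amplitude magnitude per repeated recording of the same
    placement; smaller output means more repeatable signal quality.
    """
    amps = list(per_log_amplitudes)
    if len(amps) < 2:
        raise ValueError("need at least two logs")
    if any(a <= 0 for a in amps):
        raise ValueError("amplitudes must be positive magnitudes")
    return (max(amps) - min(amps)) / max(amps)
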