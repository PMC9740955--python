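"""Distinguishing true R waves from large T waves.

When the T wave's amplitude rivals or exceeds the R wave's, amplitude
thresholding alone picks up both. Two shape measures separate them:

* the width of the peak where it crosses a fixed fraction (default 60%) of
  its own baseline-relative amplitude — T waves are substantially wider;
* the pseudo-area of the positive part of the signal in a window
  (``Area = sum of positive samples / fs``, in V*s) and its ratio to the
  window amplitude, ``RAAreaToAmpl = Area / V`` (seconds) — a duration-like
  quantity that is invariant to uniform amplitude scaling.

The validation scheme places three adjacent equal-length windows with the
candidate peak centered in the middle one, scales the window maxima by the
maximum over all three, and accepts the candidate as an R wave iff

    RAAreaToAmpl[middle] < RAAreaToAmpl[right]
    Ampl[left]  < 0.5
    Ampl[middle] >= 0.5

For a true R the right window holds the (wider) T so the middle ratio is
smaller; for a T candidate the preceding R dominates the left window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ECGSignal, SQAParams, WaveAnnotation, WindowTriplet

__all__ = [
    "PeakShape",
    "peak_width_at_threshold",
    "peak_area",
    "area_to_amplitude_ratio",
    "build_triplet",
    "validate_r_candidate",
    "discriminate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakShape:
    """Shape measures of one peak (diagnostics and shape reports)."""

    width_at_threshold: float  # s
    area: float  # V*s
    ra_area_to_ampl: float  # s

    def __post_init__(self) -> None:
        for name in ("width_at_threshold", "area", "ra_area_to_ampl"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")


def _cross_left(v: np.ndarray, peak: int, level: float) -> Optional[float]:
    """Fractional index of the last upward crossing of ``level`` before ``peak``."""
    for i in range(peak, 0, -1):
        if v[i - 1] < level <= v[i]:
            return (i - 1) + (level - v[i - 1]) / (v[i] - v[i - 1])
    return None


def _cross_right(v: np.ndarray, peak: int, level: float) -> Optional[float]:
    """Fractional index of the first downward crossing of ``level`` after ``peak``."""
    for i in range(peak, len(v) - 1):
        if v[i] >= level > v[i + 1]:
            return i + (v[i] - level) / (v[i] - v[i + 1])
    return None


def peak_width_at_threshold(
    sig: ECGSignal,
    peak: WaveAnnotation,
    threshold_fraction: float = 0.6,
) -> Optional[float]:
    """Width (s) of a positive peak at ``threshold_fraction`` of its own
    baseline-relative amplitude.

    Crossings are located by linear interpolation between samples. Returns
    ``None`` when the trace never drops below the level on either side
    within the record (degenerate/flat cases included).
    """
    if peak.amplitude <= 0:
        raise ValueError("peak must have positive baseline-relative amplitude")
    level = threshold_fraction * peak.amplitude
    left = _cross_left(sig.samples, peak.sample_index, level)
    right = _cross_right(sig.samples, peak.sample_index, level)
    if left is None or right is None:
        return None
    return (right - left) / sig.fs


def peak_area(sig: ECGSignal, window: tuple[int, int]) -> float:
    """Rectangle-rule area (V*s) of the positive part of the trace in
    ``[start, stop)`` — only the excursion above the baseline counts."""
    start, stop = window
    if not (0 <= start < stop <= sig.n_samples):
        raise ValueError(f"window [{start}, {stop}) outside record or empty")
    v = sig.samples[start:stop]
    return float(np.sum(np.maximum(v, 0.0))) / sig.fs


def area_to_amplitude_ratio(sig: ECGSignal, window: tuple[int, int]) -> float:
    """``Area / V`` (seconds): the window's positive area divided by its
    baseline-relative maximum. NaN when the window never rises above the
    baseline. Invariant to uniform amplitude scaling of the signal."""
    start, stop = window
    vmax = float(np.max(sig.samples[start:stop]))
    if vmax <= 0:
        return float("nan")
    return peak_area(sig, window) / vmax


def build_triplet(
    sig: ECGSignal, candidate: WaveAnnotation, window_len_s: float = 0.20
) -> WindowTriplet:
    """Place the three analysis windows around a candidate peak.

    The middle window is centered on the candidate; left and right windows
    are adjacent with the same length. Window maxima are scaled by the
    maximum over all three (negative maxima clip to 0 on the scaled axis);
    ratios are computed on the unscaled trace (they are scale-invariant).
    """
    wlen = int(round(window_len_s * sig.fs))
    if wlen < 2:
        raise ValueError("window too short for this sampling rate")
    m0 = candidate.sample_index - wlen // 2
    bounds = ((m0 - wlen, m0), (m0, m0 + wlen), (m0 + wlen, m0 + 2 * wlen))
    if bounds[0][0] < 0 or bounds[2][1] > sig.n_samples:
        raise ValueError("candidate too close to the record edge")
    maxima = [float(np.max(sig.samples[a:b])) for a, b in bounds]
    top = max(maxima)
    if top <= 0:
        raise ValueError("no positive excursion in any window")
    ampl = tuple(max(m, 0.0) / top for m in maxima)
    ra = tuple(area_to_amplitude_ratio(sig, b) for b in bounds)
    return WindowTriplet(bounds=bounds, ampl=ampl, ra=ra)


def validate_r_candidate(triplet: WindowTriplet, params: SQAParams | None = None) -> bool:
    """Apply the three-window acceptance conditions to a candidate.

    True iff the middle window is duration-narrower than the right one
    (ratio test) AND the left window is quiet AND the middle window carries
    the dominant amplitude. An undefined ratio (window with no positive
    excursion) fails the test.
    """
    params = params or SQAParams()
    ra_l, ra_m, ra_r = triplet.ra
    if not (np.isfinite(ra_m) and np.isfinite(ra_r)):
        log.debug("candidate rejected: undefined area-to-amplitude ratio")
        return False
    return (
        ra_m < ra_r
        and triplet.ampl[0] < params.ampl_low
        and triplet.ampl[1] >= params.ampl_high
    )


@dataclass(frozen=True)
class RejectedCandidate:
    annotation: WaveAnnotation
    reason: str


def _failure_reason(triplet: WindowTriplet, params: SQAParams) -> str:
    ra_l, ra_m, ra_r = triplet.ra
    if not (np.isfinite(ra_m) and np.isfinite(ra_r)):
        return "undefined_ratio"
    reasons = []
    if not ra_m < ra_r:
        return "middle_not_narrower_than_right"
    if not triplet.ampl[0] < params.ampl_low:
        return "left_window_too_large"
    if not triplet.ampl[1] >= params.ampl_high:
        return "middle_window_too_small"
    return "unknown"


def discriminate(
    sig: ECGSignal,
    candidates: Sequence[WaveAnnotation],
    params: SQAParams | None = None,
) -> tuple[list[WaveAnnotation], list[RejectedCandidate]]:
    """Split R candidates into validated R waves and rejected peaks.

    Each candidate gets the three-window test; candidates too close to a
    record edge to host the windows are rejected with reason ``edge``.
    The accepted set then respects the refractory constraint (larger
    amplitude wins, earlier sample breaks ties).
    """
    params = params or SQAParams()
    accepted: list[WaveAnnotation] = []
    rejected: list[RejectedCandidate] = []
    for cand in candidates:
        try:
            triplet = build_triplet(sig, cand, params.window_len_s)
        except ValueError as exc:
            log.debug("candidate at %s skipped: %s", cand.time_s, exc)
            rejected.append(RejectedCandidate(cand, "edge"))
            continue
        if validate_r_candidate(triplet, params):
            accepted.append(cand)
        else:
            rejected.append(RejectedCandidate(cand, _failure_reason(triplet, params)))

    # refractory pass over the accepted set
    order = sorted(range(len(accepted)), key=lambda i: (-accepted[i].amplitude, accepted[i].sample_index))
    min_gap = params.refractory_s * sig.fs
    kept_idx: list[int] = []
    for i in order:
        p = accepted[i].sample_index
        if all(abs(p - accepted[j].sample_index) >= min_gap for j in kept_idx):
            kept_idx.append(i)
    dropped = set(range(len(accepted))) - set(kept_idx)
    for i in sorted(dropped):
        rejected.append(RejectedCandidate(accepted[i], "refractory"))
    final = sorted((accepted[i] for i in kept_idx), key=lambda a: a.sample_index)
    rejected.sort(key=lambda r: r.annotation.sample_index)
    return final, rejected


def peak_shape(
    sig: ECGSignal,
    peak: WaveAnnotation,
    window: tuple[int, int],
    threshold_fraction: float = 0.6,
) -> PeakShape:
    """Bundle the three shape measures for one peak (shape reports)."""
    width = peak_width_at_threshold(sig, peak, threshold_fraction)
    return PeakShape(
        width_at_threshold=float("nan") if width is None else width,
        area=peak_area(sig, window),
        ra_area_to_ampl=area_to_amplitude_ratio(sig, window),
    )
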