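"""Core domain types for single-channel ECG quality analysis.

Conventions used throughout the package:

* sample indexing is 0-based and window ranges are half-open ``[start, stop)``;
* voltages are in volts and amplitudes are *baseline-relative*, i.e. measured
  against the isoelectric 0-point of the corrected trace;
* the S wave is stored with its (negative) sign on annotations and reported
  as a magnitude in :class:`FeatureSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ECGSignal",
    "WaveAnnotation",
    "WindowTriplet",
    "FeatureSet",
    "QualityReport",
    "SQAParams",
]


@dataclass
class ECGSignal:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        Voltage series in volts.
    fs
        Sampling rate in Hz.
    start_time
        Time of the first sample in seconds.
    label
        Free-text provenance tag (electrode placement, file name, preset...).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("an ECG signal needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds, ``(n_samples - 1) / fs``."""
        return (self.samples.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    def replace_samples(self, samples: np.ndarray, label: Optional[str] = None) -> "ECGSignal":
        """Same timebase, new voltage values (used by filters)."""
        return ECGSignal(
            samples=samples,
            fs=self.fs,
            start_time=self.start_time,
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class WaveAnnotation:
    """One detected fiducial point (R, S or T extremum).

    ``amplitude`` is signed and baseline-relative: R and T annotations are
    non-negative (positive extrema) and S annotations non-positive (the
    global negative extremum of the beat).
    """

    wave: str
    sample_index: int
    time_s: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.wave not in ("R", "S", "T"):
            raise ValueError(f"unknown wave label {self.wave!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be >= 0")
        if self.wave in ("R", "T") and self.amplitude < 0:
            raise ValueError(f"{self.wave} annotation must have amplitude >= 0")
        if self.wave == "S" and self.amplitude > 0:
            raise ValueError("S annotation must have amplitude <= 0")


@dataclass(frozen=True)
class WindowTriplet:
    """Three adjacent equal-length analysis windows around a peak candidate.

    ``bounds`` holds the half-open sample ranges (left, middle, right);
    ``ampl`` the window maxima scaled by the maximum over all three windows
    (so ``max(ampl) == 1``); ``ra`` the per-window area-to-amplitude ratios
    in seconds (NaN where the window has no positive excursion).
    """

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    ampl: tuple[float, float, float]
    ra: tuple[float, float, float]

    def __post_init__(self) -> None:
        (l0, l1), (m0, m1), (r0, r1) = self.bounds
        if not (l1 == m0 and m1 == r0):
            raise ValueError("windows must be adjacent")
        if not (l1 - l0 == m1 - m0 == r1 - r0 > 0):
            raise ValueError("windows must have equal positive length")
        if abs(max(self.ampl) - 1.0) > 1e-12:
            raise ValueError("scaled amplitudes must have max exactly 1")
        if any(a < 0 or a > 1 + 1e-12 for a in self.ampl):
            raise ValueError("scaled amplitudes must lie in [0, 1]")
        if any(np.isfinite(r) and r < 0 for r in self.ra):
            raise ValueError("area-to-amplitude ratios must be >= 0")


@dataclass(frozen=True)
class FeatureSet:
    """Per-recording morphology and rhythm features.

    Medians are taken over beats within the recording. RR-derived fields
    (``t_rrint``, ``r_rrint_maxmin``, ``hr_bpm``) are ``None`` when fewer
    than two beats were found.
    """

    a_rwave: Optional[float]  # median R amplitude, V
    a_twave: Optional[float]  # median T amplitude, V
    a_swave: Optional[float]  # median |S| amplitude, V (magnitude)
    t_rrint: Optional[float]  # median RR interval, s
    r_rrint_maxmin: Optional[float]  # max RR / min RR, dimensionless
    beat_count: int
    hr_bpm: Optional[float]  # 60 / t_rrint

    def __post_init__(self) -> None:
        if self.beat_count < 0:
            raise ValueError("beat_count must be >= 0")
        if self.beat_count >= 2 and self.t_rrint is not None:
            if self.r_rrint_maxmin is not None and self.r_rrint_maxmin < 1.0 - 1e-12:
                raise ValueError("r_rrint_maxmin must be >= 1")
            if self.hr_bpm is not None and abs(self.hr_bpm - 60.0 / self.t_rrint) > 1e-9:
                raise ValueError("hr_bpm must equal 60 / t_rrint")


CATEGORY_ACCEPTABLE = "acceptable"
CATEGORY_CONDITIONAL = "conditionally_acceptable"


@dataclass(frozen=True)
class QualityReport:
    """Outcome of the quality decision tree for one recording.

    ``category`` is ``"acceptable"`` or ``"conditionally_acceptable"``, or
    ``None`` with ``usable=False`` when not even the R wave was found.
    """

    category: Optional[str]
    rule_waves_visible: dict[str, bool]
    rule_hr_in_range: bool
    rule_t_not_dominant: bool
    large_t_resolved: bool
    features: FeatureSet
    usable: bool = True
    quality_grade: Optional[int] = None  # optional user-supplied visual grade

    def __post_init__(self) -> None:
        if self.category not in (None, CATEGORY_ACCEPTABLE, CATEGORY_CONDITIONAL):
            raise ValueError(f"unknown category {self.category!r}")
        if self.category is not None and not self.usable:
            raise ValueError("a categorized report must be usable")
        if self.category is not None and not self.rule_waves_visible.get("R", False):
            raise ValueError("a categorized report requires a visible R wave")
        if self.category == CATEGORY_ACCEPTABLE:
            ok = (
                all(self.rule_waves_visible.get(w, False) for w in ("R", "S", "T"))
                and self.rule_hr_in_range
                and (self.rule_t_not_dominant or self.large_t_resolved)
            )
            if not ok:
                raise ValueError("'acceptable' requires all rules to pass")


@dataclass(frozen=True)
class SQAParams:
    """Thresholds of the quality rules and the R/T discriminator.

    ``detection_threshold_fraction`` is the 60% level used both for peak
    candidate selection and for width measurement; ``ampl_low``/``ampl_high``
    are the two 0.5 constants of the three-window validation conditions,
    interpreted on the triplet's normalized amplitude scale.
    """

    hr_min: float = 40.0  # bpm
    hr_max: float = 180.0  # bpm
    detection_threshold_fraction: float = 0.6
    window_len_s: float = 0.20  # discriminator window length
    ampl_low: float = 0.5  # Ampl[left] must be strictly below this
    ampl_high: float = 0.5  # Ampl[middle] must be at or above this
    refractory_s: float = 0.200

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_threshold_fraction < 1.0):
            raise ValueError("detection_threshold_fraction must be in (0, 1)")
        if not (self.hr_min < self.hr_max):
            raise ValueError("hr_min must be below hr_max")
        if not (self.window_len_s > 0):
            raise ValueError("window_len_s must be positive")
        if not (self.refractory_s > 0):
            raise ValueError("refractory_s must be positive")
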