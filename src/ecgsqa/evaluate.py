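"""Detection scoring against ground truth: sensitivity and PPV per wave.

Truth and detection events are matched one-to-one by nearest time within a
tolerance (default 50 ms), greedily from the smallest time difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveMetrics", "match_events", "evaluate_detections"]

DEFAULT_TOLERANCE_S = 0.05


@dataclass(frozen=True)
class WaveMetrics:
    """Counts and rates for one wave type (rates in percent)."""

    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def sensitivity_pct(self) -> float:
        return float("nan") if self.n_truth == 0 else 100.0 * self.n_matched / self.n_truth

    @property
    def ppv_pct(self) -> float:
        return float("nan") if self.n_detected == 0 else 100.0 * self.n_matched / self.n_detected


def match_events(
    truth_times: np.ndarray,
    detected_times: np.ndarray,
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-time matching within ``tolerance_s``.

    Candidate pairs are sorted by absolute time difference (ties broken by
    indices) and assigned greedily; each truth event and each detection is
    used at most once. Returns (truth_index, detected_index) pairs.
    """
    truth_times = np.asarray(truth_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    pairs = []
    for i, tt in enumerate(truth_times):
        dt = np.abs(detected_times - tt)
        for j in np.nonzero(dt <= tolerance_s)[0]:
            pairs.append((float(dt[j]), i, int(j)))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j))
    matches.sort()
    return matches


def evaluate_detections(
    truth_by_wave: dict[str, np.ndarray],
    detected_by_wave: dict[str, np.ndarray],
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> dict[str, WaveMetrics]:
    """Per-wave sensitivity/PPV for time-stamped truth and detections."""
    out = {}
    for wave in sorted(set(truth_by_wave) | set(detected_by_wave)):
        tt = np.asarray(truth_by_wave.get(wave, []), dtype=float)
        dd = np.asarray(detected_by_wave.get(wave, []), dtype=float)
        matches = match_events(tt, dd, tolerance_s)
        out[wave] = WaveMetrics(n_truth=tt.size, n_detected=dd.size, n_matched=len(matches))
    return out
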