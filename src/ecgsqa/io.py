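"""Readers and writers for signals, annotations and quality reports.

Signal CSV: one column (voltage_V; sampling rate must be supplied) or two
columns (time_s, voltage_V; sampling rate inferred from the timebase).
Annotation CSV: ``sample_index,time_s,wave,amplitude_V``. Reports are JSON.
All CSV output is comma-separated with '.' decimals and a mandatory header;
input headers are optional.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ECGSignal, FeatureSet, QualityReport, WaveAnnotation

__all__ = [
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "read_report",
    "write_report",
]

#: Maximum tolerated relative deviation of a time step from the median step.
UNIFORMITY_TOL = 0.01


def _looks_numeric(row: Sequence[str]) -> bool:
    try:
        for item in row:
            float(item)
    except (TypeError, ValueError):
        return False
    return True


def read_signal(
    path: Union[str, Path],
    fs_override: Optional[float] = None,
    label: Optional[str] = None,
) -> ECGSignal:
    """Read a one- or two-column voltage CSV into an :class:`ECGSignal`.

    For two-column input the sampling rate is the reciprocal of the median
    time step; a timebase whose steps deviate from that median by more than
    1% is rejected as non-uniform. If ``fs_override`` conflicts with an
    inferred timebase, the timebase wins and a warning is issued.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    # header row is optional on input: sniff the first line
    with open(path) as fh:
        first = fh.readline().strip()
    if not first:
        raise ValueError(f"empty signal file: {path}")
    has_header = not _looks_numeric(first.split(","))
    df = pd.read_csv(path, header=0 if has_header else None, float_precision="round_trip")
    if df.shape[0] < 2:
        raise ValueError("signal file must contain at least 2 samples")
    if df.shape[1] not in (1, 2):
        raise ValueError(f"expected 1 or 2 columns, found {df.shape[1]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric rows in {path}: {exc}") from exc

    if df.shape[1] == 1:
        if fs_override is None:
            raise ValueError("sampling rate required for single-column input")
        return ECGSignal(values[:, 0], fs=fs_override, label=label or path.name)

    t, v = values[:, 0], values[:, 1]
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise ValueError("time column must be strictly increasing")
    if np.max(np.abs(dt - step)) > UNIFORMITY_TOL * step:
        raise ValueError("non-uniform timebase (step deviation exceeds 1%)")
    fs = 1.0 / step
    if fs_override is not None and abs(fs_override - fs) > UNIFORMITY_TOL * fs:
        warnings.warn(
            f"fs override {fs_override} Hz conflicts with the file timebase "
            f"({fs:.6g} Hz); the timebase wins",
            stacklevel=2,
        )
    return ECGSignal(v, fs=fs, start_time=float(t[0]), label=label or path.name)


def write_signal(signal: ECGSignal, path: Union[str, Path]) -> None:
    """Write a two-column (time_s, voltage_V) CSV."""
    df = pd.DataFrame({"time_s": signal.times, "voltage_V": signal.samples})
    # 17 significant digits round-trip IEEE doubles losslessly
    df.to_csv(path, index=False, float_format="%.17g")


def write_annotations(
    annotations: Sequence[WaveAnnotation], path: Union[str, Path]
) -> None:
    """Write annotations as ``sample_index,time_s,wave,amplitude_V`` CSV.

    The input must already be sorted by sample index.
    """
    idx = [a.sample_index for a in annotations]
    if any(b < a for a, b in zip(idx, idx[1:])):
        raise ValueError("annotations must be sorted by sample_index")
    df = pd.DataFrame(
        {
            "sample_index": idx,
            "time_s": [a.time_s for a in annotations],
            "wave": [a.wave for a in annotations],
            "amplitude_V": [a.amplitude for a in annotations],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_annotations(path: Union[str, Path]) -> list[WaveAnnotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_index", "time_s", "wave", "amplitude_V"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file missing columns {required - set(df.columns)}")
    return [
        WaveAnnotation(
            wave=str(row.wave),
            sample_index=int(row.sample_index),
            time_s=float(row.time_s),
            amplitude=float(row.amplitude_V),
        )
        for row in df.itertuples()
    ]


_FEATURE_UNITS = {
    "a_rwave": "V",
    "a_twave": "V",
    "a_swave": "V",
    "t_rrint": "s",
    "r_rrint_maxmin": "ratio",
    "beat_count": "beats",
    "hr_bpm": "bpm",
}


def write_report(report: QualityReport, path: Union[str, Path]) -> None:
    """Serialize a quality report to JSON (machine-checkable rules section)."""
    feats = dataclasses.asdict(report.features)
    doc = {
        "category": report.category,
        "usable": report.usable,
        "rules": {
            "waves_visible": report.rule_waves_visible,
            "hr_in_range": report.rule_hr_in_range,
            "t_not_dominant": report.rule_t_not_dominant,
            "large_t_resolved": report.large_t_resolved,
        },
        "features": {k: {"value": feats[k], "unit": _FEATURE_UNITS[k]} for k in feats},
    }
    if report.quality_grade is not None:
        doc["quality_grade"] = report.quality_grade
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: Union[str, Path]) -> QualityReport:
    with open(path) as fh:
        doc = json.load(fh)
    feats = {k: v["value"] for k, v in doc["features"].items()}
    return QualityReport(
        category=doc["category"],
        rule_waves_visible=dict(doc["rules"]["waves_visible"]),
        rule_hr_in_range=bool(doc["rules"]["hr_in_range"]),
        rule_t_not_dominant=bool(doc["rules"]["t_not_dominant"]),
        large_t_resolved=bool(doc["rules"]["large_t_resolved"]),
        features=FeatureSet(**feats),
        usable=bool(doc.get("usable", True)),
        quality_grade=doc.get("quality_grade"),
    )
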