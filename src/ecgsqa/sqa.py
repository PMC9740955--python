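"""Quality categorization and the full analysis pipeline.

A recording is **acceptable** when all three waves (R, S, T) are visible,
the heart rate lies in the plausible 40-180 bpm band, and the T wave does
not dominate the R wave — unless the R/T discriminator has positively
resolved the large-T situation, in which case dominance alone does not
demote the record. Anything short of that, with a visible R wave, is
**conditionally acceptable**: the RR interval (hence heart rate) is still
recoverable. Without a recognizable R wave the record is flagged unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    CATEGORY_ACCEPTABLE,
    CATEGORY_CONDITIONAL,
    ECGSignal,
    FeatureSet,
    QualityReport,
    SQAParams,
    WaveAnnotation,
)
from .discriminator import RejectedCandidate, discriminate
from .fiducials import (
    DetectionParams,
    compute_features,
    detect_r_peaks,
    detect_s_wave,
    detect_t_wave,
    rr_intervals,
)
from .preprocess import PreprocessParams, preprocess

__all__ = ["apply_rules", "analyze_record", "AnalysisResult"]

log = logging.getLogger(__name__)

#: Fraction of beats that must yield a wave annotation for that wave to
#: count as "visible".
VISIBILITY_FRACTION = 0.5


def apply_rules(
    features: FeatureSet,
    waves_visible: dict[str, bool],
    large_t_resolved: bool = False,
    params: SQAParams | None = None,
    quality_grade: Optional[int] = None,
) -> QualityReport:
    """Categorize a recording from its features and wave visibility.

    Rules: (1) all chosen waves visible; (2) heart rate within
    [hr_min, hr_max] bpm; (3) T amplitude not larger than R amplitude,
    overridable by a successful discriminator pass.
    """
    params = params or SQAParams()
    visible = {w: bool(waves_visible.get(w, False)) for w in ("R", "S", "T")}
    hr = features.hr_bpm
    hr_ok = hr is not None and params.hr_min <= hr <= params.hr_max
    if features.a_twave is None or features.a_rwave is None:
        t_ok = True  # dominance cannot be asserted without both amplitudes
    else:
        t_ok = features.a_twave <= features.a_rwave

    if not visible["R"]:
        log.warning("no recognizable R wave: record unusable")
        return QualityReport(
            category=None,
            rule_waves_visible=visible,
            rule_hr_in_range=hr_ok,
            rule_t_not_dominant=t_ok,
            large_t_resolved=large_t_resolved,
            features=features,
            usable=False,
            quality_grade=quality_grade,
        )
    acceptable = all(visible.values()) and hr_ok and (t_ok or large_t_resolved)
    return QualityReport(
        category=CATEGORY_ACCEPTABLE if acceptable else CATEGORY_CONDITIONAL,
        rule_waves_visible=visible,
        rule_hr_in_range=hr_ok,
        rule_t_not_dominant=t_ok,
        large_t_resolved=large_t_resolved,
        features=features,
        usable=True,
        quality_grade=quality_grade,
    )


@dataclass
class AnalysisResult:
    """Everything the pipeline produced for one recording."""

    annotations: list[WaveAnnotation]
    features: FeatureSet
    report: QualityReport
    rejected: list[RejectedCandidate] = field(default_factory=list)
    preprocessed: Optional[ECGSignal] = None


def analyze_record(
    sig: ECGSignal,
    detection: DetectionParams | None = None,
    sqa_params: SQAParams | None = None,
    preprocess_params: PreprocessParams | None = None,
    use_preprocess: bool = True,
    use_discriminator: bool = True,
    quality_grade: Optional[int] = None,
) -> AnalysisResult:
    """Run the full pipeline: denoise, detect, discriminate, categorize.

    ``use_discriminator=False`` reproduces plain threshold R detection,
    which miscounts large T waves as beats; ``use_preprocess=False`` feeds
    the raw trace straight to the detectors (for already-clean data).
    Deterministic for fixed input and parameters.
    """
    detection = detection or DetectionParams()
    sqa_params = sqa_params or SQAParams()

    work = preprocess(sig, preprocess_params) if use_preprocess else sig

    candidates = detect_r_peaks(work, detection)
    if use_discriminator:
        r_waves, rejected_c = discriminate(work, candidates, sqa_params)
    else:
        r_waves, rejected_c = list(candidates), []

    annotations: list[WaveAnnotation] = list(r_waves)
    n_s = n_t = 0
    for i, r in enumerate(r_waves):
        next_r = r_waves[i + 1] if i + 1 < len(r_waves) else None
        s = detect_s_wave(work, r, detection)
        if s is not None:
            annotations.append(s)
            n_s += 1
        t = detect_t_wave(work, r, detection, next_r=next_r)
        if t is not None:
            annotations.append(t)
            n_t += 1
    annotations.sort(key=lambda a: a.sample_index)

    rr = rr_intervals(r_waves)
    features = compute_features(annotations, rr)

    n_beats = len(r_waves)
    visible = {
        "R": n_beats > 0,
        "S": n_beats > 0 and n_s >= VISIBILITY_FRACTION * n_beats,
        "T": n_beats > 0 and n_t >= VISIBILITY_FRACTION * n_beats,
    }
    # the large-T situation counts as resolved when the discriminator ran
    # and actively rejected wide peaks while keeping a plausible beat set
    large_t_resolved = use_discriminator and any(
        rej.reason != "edge" for rej in rejected_c
    )
    report = apply_rules(
        features, visible, large_t_resolved, sqa_params, quality_grade
    )
    return AnalysisResult(
        annotations=annotations,
        features=features,
        report=report,
        rejected=rejected_c,
        preprocessed=work if use_preprocess else None,
    )
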