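"""Shape measures and the three-window R/T discrimination rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgsqa import (
    ECGSignal,
    SQAParams,
    WaveAnnotation,
    WindowTriplet,
    area_to_amplitude_ratio,
    build_triplet,
    detect_r_peaks,
    discriminate,
    peak_area,
    peak_width_at_threshold,
    validate_r_candidate,
)
from ecgsqa.evaluate import evaluate_detections
from ecgsqa.synthetic import SynthConfig, generate_ecg, preset
from conftest import gaussian_pulse

FS = 1000.0


def peak_of(sig):
    i = int(np.argmax(sig.samples))
    return WaveAnnotation("R", i, i / sig.fs, float(sig.samples[i]))


class TestWidthAtThreshold:
    def test_triangle_similar_triangles(self):
        t = np.arange(0, 0.4, 1 / FS)
        tri = np.maximum(0.0, 1.0 - np.abs(t - 0.2) / 0.1)  # base 0.2 s
        sig = ECGSignal(tri, FS)
        width = peak_width_at_threshold(sig, peak_of(sig), 0.6)
        assert width == pytest.approx(0.4 * 0.2, rel=1e-6)

    def test_gaussian_closed_form(self):
        sigma = 0.020
        sig = gaussian_pulse(sigma, FS)
        width = peak_width_at_threshold(sig, peak_of(sig), 0.6)
        expected = 2 * sigma * np.sqrt(2 * np.log(1 / 0.6))
        assert width == pytest.approx(expected, rel=5e-3)

    def test_gaussian_bisection_oracle(self):
        """Independent oracle: bisect the continuous Gaussian for the
        crossing abscissa instead of interpolating samples."""
        from scipy.optimize import brentq

        sigma = 0.020
        sig = gaussian_pulse(sigma, FS)
        width = peak_width_at_threshold(sig, peak_of(sig), 0.6)
        x = brentq(lambda u: np.exp(-0.5 * (u / sigma) ** 2) - 0.6, 0, 5 * sigma)
        assert width == pytest.approx(2 * x, rel=5e-3)

    def test_flat_signal_undefined(self):
        sig = ECGSignal(np.full(1000, 0.5), FS)
        peak = WaveAnnotation("R", 500, 0.5, 0.5)
        assert peak_width_at_threshold(sig, peak) is None

    def test_requires_positive_amplitude(self):
        sig = gaussian_pulse(0.02, FS)
        with pytest.raises(ValueError, match="positive"):
            peak_width_at_threshold(sig, WaveAnnotation("S", 10, 0.01, -0.1))


class TestPeakArea:
    def test_zero_window(self):
        assert peak_area(ECGSignal(np.zeros(100), FS), (0, 100)) == 0.0

    def test_rectangle_identity(self):
        v = np.zeros(400)
        v[100:200] = 1.0  # 1 V for 0.1 s
        area = peak_area(ECGSignal(v, FS), (0, 400))
        assert area == pytest.approx(0.1, abs=1.5 / FS)

    def test_half_sine_vs_fine_trapezoid(self):
        d = 0.1
        t = np.arange(0, d, 1 / FS)
        pulse = np.concatenate([np.zeros(50), np.sin(np.pi * t / d), np.zeros(50)])
        area = peak_area(ECGSignal(pulse, FS), (0, pulse.size))
        # oracle: trapezoidal integration at 10x resolution
        t10 = np.arange(0, d, 1 / (10 * FS))
        oracle = np.trapezoid(np.sin(np.pi * t10 / d), t10)
        assert area == pytest.approx(oracle, rel=5e-3)

    def test_negative_part_excluded(self):
        v = np.concatenate([np.full(100, -1.0), np.full(100, 2.0)])
        assert peak_area(ECGSignal(v, FS), (0, 200)) == pytest.approx(0.2)

    def test_small_window_equals_bruteforce(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 64)
        sig = ECGSignal(v, FS)
        acc = 0.0
        for x in v:  # brute-force per-sample accumulation
            if x > 0:
                acc += x
        assert peak_area(sig, (0, 64)) == acc / FS

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_area(ECGSignal(np.zeros(100), FS), (50, 50))


class TestAreaToAmplitudeRatio:
    def test_rectangle_height_cancels(self):
        for height in (0.2, 1.0, 7.5):
            v = np.zeros(400)
            v[100:200] = height
            ra = area_to_amplitude_ratio(ECGSignal(v, FS), (0, 400))
            assert ra == pytest.approx(0.1, abs=1.5 / FS)

    def test_half_sine_value(self):
        d = 0.1
        t = np.arange(0, d, 1 / FS)
        pulse = np.concatenate([np.zeros(50), np.sin(np.pi * t / d), np.zeros(50)])
        ra = area_to_amplitude_ratio(ECGSignal(pulse, FS), (0, pulse.size))
        assert ra == pytest.approx(2 / np.pi * d, rel=5e-3)

    def test_undefined_without_positive_excursion(self):
        assert np.isnan(area_to_amplitude_ratio(ECGSignal(np.full(100, -1.0), FS), (0, 100)))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, c):
        sigma = 0.02
        sig = gaussian_pulse(sigma, FS)
        scaled = ECGSignal(sig.samples * c, FS)
        window = (0, sig.n_samples)
        assert area_to_amplitude_ratio(sig, window) == pytest.approx(
            area_to_amplitude_ratio(scaled, window), abs=1e-12, rel=1e-12
        )

    def test_gaussian_ra_tracks_sigma(self):
        """With the wave fully inside the window, Area/V ~ sigma*sqrt(2*pi),
        so the T/R ratio of the measure tracks sigma_T / sigma_R."""
        for sigma in (0.018, 0.055):
            sig = gaussian_pulse(sigma, FS)
            ra = area_to_amplitude_ratio(sig, (0, sig.n_samples))
            assert ra == pytest.approx(sigma * np.sqrt(2 * np.pi), rel=1e-3)


class TestBuildTriplet:
    def test_lone_feature_gives_0_1_0(self):
        sig = gaussian_pulse(0.018, FS, pad_s=0.6)
        trip = build_triplet(sig, peak_of(sig), 0.20)
        assert trip.ampl == pytest.approx((0.0, 1.0, 0.0))

    def test_identical_pulses_tie(self):
        v = np.zeros(2000)
        t = np.arange(2000) / FS
        for c in (1.0, 1.25):  # middle and right windows
            v += np.exp(-0.5 * ((t - c) / 0.02) ** 2)
        sig = ECGSignal(v, FS)
        cand = WaveAnnotation("R", 1000, 1.0, float(v[1000]))
        trip = build_triplet(sig, cand, 0.20)
        assert trip.ampl[1] == pytest.approx(1.0)
        assert trip.ampl[2] == pytest.approx(1.0, abs=1e-3)

    def test_normal_beat_right_window_sees_t(self):
        cfg = SynthConfig(morphology="normal", hr_bpm=60, duration_s=12,
                          fs=FS, seed=1, hr_jitter_frac=0.0)
        sig, truth = generate_ecg(cfg)
        m = preset("normal")
        r = detect_r_peaks(sig)[5]
        trip = build_triplet(sig, r, 0.20)
        assert trip.ampl[1] == pytest.approx(1.0)
        assert trip.ampl[2] == pytest.approx(m.t.amplitude / m.r.amplitude, rel=0.05)

    def test_edge_candidate_rejected(self):
        sig = gaussian_pulse(0.018, FS, pad_s=0.25)
        cand = WaveAnnotation("R", 10, 0.01, 0.5)
        with pytest.raises(ValueError, match="edge"):
            build_triplet(sig, cand, 0.20)


class TestValidateRCandidate:
    def _triplet(self, ampl, ra):
        return WindowTriplet(((0, 10), (10, 20), (20, 30)), ampl, ra)

    @pytest.mark.parametrize(
        "ampl, ra, expected",
        [
            ((0.3, 1.0, 0.8), (0.02, 0.02, 0.05), True),
            ((0.6, 1.0, 0.8), (0.02, 0.02, 0.05), False),  # left too large
            ((0.3, 1.0, 0.8), (0.02, 0.06, 0.05), False),  # middle not narrower
            ((1.0, 0.4, 0.8), (0.02, 0.02, 0.05), False),  # middle too small
        ],
    )
    def test_rule_table(self, ampl, ra, expected):
        assert validate_r_candidate(self._triplet(ampl, ra)) is expected

    def test_undefined_ratio_fails(self):
        trip = self._triplet((0.3, 1.0, 0.0), (0.02, 0.02, float("nan")))
        assert validate_r_candidate(trip) is False


class TestDiscriminate:
    def test_empty_candidates(self):
        sig = gaussian_pulse(0.018, FS)
        assert discriminate(sig, []) == ([], [])

    def test_large_t_fully_separated(self, clean_large_t):
        cfg, sig, truth = clean_large_t
        assert truth.beat_count >= 60
        candidates = detect_r_peaks(sig)
        assert len(candidates) > truth.beat_count  # T waves picked up too
        accepted, rejected = discriminate(sig, candidates)
        det = np.array([a.time_s for a in accepted])
        m = evaluate_detections({"R": truth.r_times}, {"R": det})["R"]
        assert m.sensitivity_pct == 100.0
        assert m.ppv_pct == 100.0
        assert all(r.reason != "edge" for r in rejected[1:-1])

    def test_noop_on_normal_preset(self):
        cfg = SynthConfig(morphology="normal", hr_bpm=70, duration_s=30,
                          fs=FS, seed=3)
        sig, _ = generate_ecg(cfg)
        candidates = detect_r_peaks(sig)
        accepted, rejected = discriminate(sig, candidates)
        assert accepted == candidates
        assert rejected == []

    def test_signal_scaling_changes_no_outcome(self, clean_large_t):
        _, sig, _ = clean_large_t
        candidates = detect_r_peaks(sig)
        accepted, _ = discriminate(sig, candidates)
        scaled_sig = ECGSignal(sig.samples * 3.7, sig.fs)
        scaled_cands = [
            WaveAnnotation(a.wave, a.sample_index, a.time_s, a.amplitude * 3.7)
            for a in candidates
        ]
        accepted_scaled, _ = discriminate(scaled_sig, scaled_cands)
        assert [a.sample_index for a in accepted_scaled] == [
            a.sample_index for a in accepted
        ]

    def test_time_dilation_covariance(self):
        """Resampling by k multiplies widths and ratios by k and flips no
        Boolean outcome (windows scaled accordingly)."""
        k = 2.0
        sigma = 0.02
        base = gaussian_pulse(sigma, FS, pad_s=0.6)
        dilated = gaussian_pulse(sigma * k, FS, pad_s=0.6 * k)

        w_base = peak_width_at_threshold(base, peak_of(base))
        w_dil = peak_width_at_threshold(dilated, peak_of(dilated))
        assert w_dil == pytest.approx(k * w_base, rel=1e-3)

        ra_base = area_to_amplitude_ratio(base, (0, base.n_samples))
        ra_dil = area_to_amplitude_ratio(dilated, (0, dilated.n_samples))
        assert ra_dil == pytest.approx(k * ra_base, rel=1e-3)

        trip_base = build_triplet(base, peak_of(base), 0.2)
        trip_dil = build_triplet(dilated, peak_of(dilated), 0.2 * k)
        assert validate_r_candidate(trip_base) == validate_r_candidate(trip_dil)
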