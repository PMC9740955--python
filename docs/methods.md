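# Methods

## Signal model and conventions

All analysis operates on a uniformly sampled single-channel voltage trace.
Amplitudes are baseline-relative: the isoelectric level (0-point) of the
corrected trace is 0 V, R and T annotations are positive extrema, the S
annotation is the negative extremum after the R apex (stored signed,
reported as a magnitude in feature tables). Sample indexing is 0-based and
all window ranges are half-open `[start, stop)`, which makes the three
adjacent discriminator windows unambiguous.

## Synthetic generator

Each beat is a sum of five Gaussian components (P, Q, R, S, T), with
signed amplitude `a_w` (V), width `sigma_w` (s) and latency `theta_w` (s)
relative to the R apex. Gaussians were chosen over dynamical-system ECG
models because every quantity the analysis measures — peak amplitude,
width at a fractional threshold, area above baseline — has a closed form
(width at the 60% level is `2*sigma*sqrt(2*ln(1/0.6))`; the
area-to-amplitude ratio of a fully contained Gaussian is
`sigma*sqrt(2*pi)`), so detector output can be checked against analytic
oracles rather than against another detector.

Default morphology (`normal` preset):

| wave | a (V)  | sigma (s) | theta (s) |
|------|--------|-----------|-----------|
| P    | 0.080  | 0.025     | -0.220    |
| Q    | -0.050 | 0.012     | -0.040    |
| R    | 0.665  | 0.018     | 0.000     |
| S    | -0.368 | 0.015     | +0.060    |
| T    | 0.246  | 0.055     | +0.300    |

R and T amplitudes reproduce a standard-lead T/R amplitude ratio of ~0.37;
sigma_R = 18 ms and sigma_T = 55 ms give a QRS of roughly 90-110 ms and a
T duration of ~180 ms, within textbook adult ranges. The S latency of
60 ms keeps the R Gaussian's contribution at the S extremum below 1%, so
the superposed extremum stays within 2% of the component amplitude. The
`weak_arm` preset scales all amplitudes so a_R ≈ 0.17 V (single-arm
signal strength); `large_t` sets a_T = 1.2·a_R, the regime that defeats
plain thresholding. Ground truth records the extrema of the *superposed*
noise-free waveform (located on a 10 µs grid), not the bare component
amplitudes.

Beats are placed at RR intervals drawn from a normal distribution with
mean `60/hr_bpm` and fractional standard deviation `hr_jitter_frac`
(default 0.03, a resting-state RR variability of a few percent typical of
healthy adults), truncated below at 0.3 s so consecutive beats cannot
overlap. A 0.5 s margin at each record end stays beat-free, which also
guarantees the discriminator windows always fit. Noise terms — white
Gaussian noise, a powerline sinusoid (default 50 Hz) with random phase,
and sinusoidal baseline wander (default 0.3 Hz) — are added after
placement; identical configurations are bit-identical under a fixed seed.

What the generator does **not** emulate: motion artifacts, electrode
pop/contact loss, inverted/biphasic/flattened T morphologies, ectopic
beats, and respiratory amplitude modulation. Passing tests on this data
therefore demonstrate correctness of the *operators* (detection, shape
measurement, rule logic) under the stated morphology family, not clinical
robustness on ambulatory recordings.

## Preprocessing

* **Savitzky–Golay smoothing** — default 25 ms window, order 3: short
  enough to leave the 18 ms-sigma R apex essentially unattenuated while
  suppressing wideband noise.
* **Powerline removal** — an IIR notch (`scipy.signal.iirnotch`,
  Q = 30) applied forward-backward (zero phase). The designed response is
  ≥ 40 dB down at the mains frequency with < 1 dB ripple outside ±2 Hz;
  the two-pass application doubles the dB attenuation.
* **Baseline (0-point) correction** — a two-stage median filter: a
  window of one third of `baseline_window_s` (default 0.6 s) flattens the
  QRS complexes, the full window then tracks only the slow drift, which is
  subtracted; any residual median offset is folded into the returned
  baseline estimate so the corrected trace's median is exactly 0. Median
  filtering is nonlinear: with strong mains content the baseline stage
  must run *after* the notch (the default order smoothing → notch →
  baseline does this); with only slow wander present, all stage orders
  agree to well under 2% RMS.

All stages preserve length and sampling rate and use mirror padding.
Preprocessing can be bypassed entirely (`use_preprocess=False` /
`--no-preprocess`) for data that is already clean — the parameter-recovery
checks do this, so they measure the detector rather than smoothing bias.

## Detection

R candidates are local maxima above `threshold_fraction` (default 0.6) of
the record's **global** positive extremum — one horizontal threshold for
the whole trace, not per-beat adaptive — thinned by a 200 ms refractory
period (larger amplitude wins; equal amplitudes keep the earlier sample).
The S wave is the minimum within 80 ms after each accepted R (returned
only if below baseline); the T wave is the maximum within 0.12–0.45 s
after the R, truncated at the next R minus the refractory period, returned
only if above baseline. Search windows that would run past the record end
return no annotation. The S/T windows are fixed physiologically plausible
defaults, exposed as parameters.

## R/T discrimination

Three adjacent windows of `window_len_s` (default 0.20 s — long enough to
contain a full T wave at the default morphology, short enough that the
triplet spans less than two beats at ≤ 180 bpm), middle window centered on
the candidate. Window maxima are scaled by the maximum over the three
windows, so the 0.5 amplitude constants of the acceptance conditions act
on a normalized scale; the area-to-amplitude ratios are computed on the
unscaled trace, which is equivalent because the ratio is provably
scale-invariant. The area uses rectangle-rule summation of the positive
samples only. Acceptance requires all three conditions (middle ratio
smaller than right, left amplitude < 0.5, middle amplitude ≥ 0.5); only
the right window's ratio enters the rule, exactly as the validation
conditions state. Candidates whose windows would cross a record edge are
rejected with reason `edge`; the accepted set gets a final refractory
pass. Width at the 60% level is computed per peak for reporting but is
deliberately not part of the accept/reject rule.

Rejected T-shaped candidates are not re-labeled directly; the subsequent
T-wave search from each accepted R finds the same extremum, which keeps
the labeling single-sourced.

## Quality categorization

A wave counts as visible when at least 50% of detected beats yield that
annotation (the visibility notion is otherwise qualitative; 50% makes it
operational). The category is **acceptable** iff all of R, S, T are
visible AND 40 ≤ HR ≤ 180 bpm AND (T amplitude ≤ R amplitude OR the
discriminator actively resolved a large-T situation); otherwise
**conditionally acceptable** provided R is visible; with no recognizable R
wave the record is flagged unusable (no category). T dominance with an
*unresolved* discriminator demotes the record; a successful discriminator
pass merely flags it — the T > R morphology can be a placement effect
rather than a defect. HR is 60/median(RR) in bpm; the beat count is
reported separately, since on short logs a count and a rate are easy to
conflate.

## Evaluation harness

Detections are scored against ground truth by greedy nearest-time
one-to-one matching within a 50 ms tolerance; sensitivity is matched
truth over total truth, positive predictivity matched detections over
total detections, per wave.

## Numerical choices

Threshold crossings for width measurement are located by linear
interpolation between samples. Ties in the refractory pass keep the
earlier sample. Single-column CSV input requires an explicit sampling
rate; two-column input infers it from the median time step and rejects
timebases whose steps deviate by more than 1% (an explicit rate that
conflicts with an inferred timebase loses, with a warning). CSV floats are
written with 17 significant digits and read in round-trip precision mode,
so write/read cycles are lossless. Supported inputs are CSV and in-memory
arrays; multi-lead container formats are out of scope.

## Problem sizes

The test suite and the acceptance script use records of 10–60 s at
500–1000 Hz (50–62 beats per record, ten seeds for the discriminator
sweep), sizes at which every quantity of interest is already stable; the
full suite runs in a few seconds.

## Known limitations

The discriminator addresses the large-T regime only; inverted, biphasic
and flattened T waves are out of scope. The single global detection
threshold assumes roughly stationary R amplitude across the record.
Quality categorization assumes sinus-like rhythm; arrhythmia
classification is not attempted.
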