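# ecgsqa

Signal-quality assessment for single-channel ECG recorded from
**non-standard electrode placements** — thoracic pairs co-located with
impedance-cardiography electrodes, single-arm placements, and other
wearable-oriented configurations whose waveforms deviate from textbook
lead morphology. It is aimed at researchers evaluating candidate electrode
positions and at developers of wearable acquisition front-ends who need an
automatic, rule-based answer to "is this trace usable?".

## What it computes

From a baseline-corrected voltage trace the package extracts the R, S and
T fiducial points and the per-recording features

- A_Rwave, A_Twave, A_Swave — median baseline-relative wave amplitudes (V),
- T_RRint — median RR interval (s), and HR = 60 / T_RRint (bpm),
- R_RRintmaxmin — max(RR)/min(RR), a rhythm-consistency ratio ≥ 1,

and categorizes the recording by three rules (all waves visible; HR in
40–180 bpm; T not dominating R) as **acceptable** or **conditionally
acceptable** (R visible, so heart rate is still recoverable).

Its centerpiece handles the placement-induced **large-T regime**
(A_T ≳ A_R), where plain amplitude thresholding counts every T wave as a
beat. Each R candidate gets three adjacent windows (candidate centered in
the middle one). With window amplitudes scaled by the maximum over the
three windows, and with the pseudo-area of the positive part of the signal
`Area = Σ max(V_i, 0) / f_s` and `RAAreaToAmpl = Area / V_max` (seconds,
scale-invariant), a candidate is accepted as an R wave iff

```
RAAreaToAmpl[middle] < RAAreaToAmpl[right]
Ampl[left]  < 0.5
Ampl[middle] ≥ 0.5
```

T waves fail the test because they are wider (larger area per amplitude)
and because the preceding R wave lights up their left window. Peak width
at the 60% threshold level is reported per beat as a diagnostic.

A Gaussian-sum synthetic generator (presets `normal`, `weak_arm`,
`large_t`) produces annotated recordings with exact ground truth, so every
stage is testable without recorded data.

## Worked example

`python examples/large_t_discrimination.py` generates a clean 62-beat
recording whose T amplitude is 1.2× the R amplitude and analyzes it twice:

```
true beats: 62
threshold only      beats 124  RR max/min 2.510  category conditionally_acceptable
with discriminator  beats  62  RR max/min 1.110  category acceptable
discriminated R detection: sensitivity 100.0%  PPV 100.0%
```

Thresholding alone doubles the beat count (every T counted as an R) and
inflates the RR max/min ratio beyond 2; the three-window test rejects all
T candidates and recovers the true rhythm, after which the record is
acceptable. The other scripts in `examples/` cover the noisy end-to-end
pipeline, per-beat width/area tables, and the decision tree.

The same functionality is available from a shell:

```
ecgsqa simulate --preset large_t --seed 11 --duration 62 --fs 500 \
       --out-signal sig.csv --out-truth truth.csv
ecgsqa analyze sig.csv --out-annotations ann.csv --out-report report.json
ecgsqa evaluate truth.csv ann.csv
ecgsqa shape-report sig.csv --out shapes.csv
```

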