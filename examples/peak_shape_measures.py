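"""Per-beat shape measures separating R from T waves.

Width at the 60% threshold level and the pseudo-area of the positive part
of the signal are the two measures the discriminator builds on: T waves
are both wider and carry more area-per-amplitude than R waves.
"""

import numpy as np

from ecgsqa import analyze_record, peak_area, peak_width_at_threshold
from ecgsqa.synthetic import SynthConfig, generate_ecg

config = SynthConfig(morphology="normal", hr_bpm=60, hr_jitter_frac=0.0,
                     duration_s=7, fs=1000, seed=1)
signal, _ = generate_ecg(config)
result = analyze_record(signal, use_preprocess=False)
r_waves = [a for a in result.annotations if a.wave == "R"]
t_waves = [a for a in result.annotations if a.wave == "T"]

half = 100  # samples: 0.2 s window around each peak
print("beat   R width   T width   R area    T area     (s / V*s)")
ratios = []
for i, (r, t) in enumerate(zip(r_waves, t_waves)):
    w_r = peak_width_at_threshold(signal, r, 0.6)
    w_t = peak_width_at_threshold(signal, t, 0.6)
    a_r = peak_area(signal, (r.sample_index - half, r.sample_index + half))
    a_t = peak_area(signal, (t.sample_index - half, t.sample_index + half))
    ratios.append(w_t / w_r)
    print(f"{i:4d}   {w_r:.4f}    {w_t:.4f}    {a_r:.4f}    {a_t:.4f}")
print(f"\nmean T/R width ratio: {np.mean(ratios):.2f}")
# The T wave is ~3x wider than the R wave at the 60% level on this
# morphology, which is what makes the width/area test discriminative.
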