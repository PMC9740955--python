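"""The large-T failure mode and its repair by the three-window test.

On some electrode placements the T wave grows as large as the R wave, so
plain amplitude thresholding counts every T as an extra beat: the beat
count roughly doubles and the RR max/min ratio explodes. The discriminator
compares each candidate's area-to-amplitude ratio and its neighbours'
scaled amplitudes to reject the wide T peaks.
"""

import numpy as np

from ecgsqa import analyze_record
from ecgsqa.evaluate import evaluate_detections
from ecgsqa.synthetic import SynthConfig, generate_ecg

config = SynthConfig(morphology="large_t", hr_bpm=60, duration_s=62, fs=500, seed=11)
signal, truth = generate_ecg(config)

plain = analyze_record(signal, use_preprocess=False, use_discriminator=False)
fixed = analyze_record(signal, use_preprocess=False, use_discriminator=True)

print(f"true beats: {truth.beat_count}")
for name, res in (("threshold only     ", plain), ("with discriminator ", fixed)):
    f = res.features
    print(f"{name} beats {f.beat_count:3d}  RR max/min {f.r_rrint_maxmin:.3f}  "
          f"category {res.report.category}")

det = np.array([a.time_s for a in fixed.annotations if a.wave == "R"])
m = evaluate_detections({"R": truth.r_times}, {"R": det})["R"]
print(f"discriminated R detection: sensitivity {m.sensitivity_pct:.1f}%  "
      f"PPV {m.ppv_pct:.1f}%")
# Without the discriminator every T is miscounted as a beat (RR max/min > 2);
# with it the true beat count and steady rhythm are recovered exactly.
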