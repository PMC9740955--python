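"""The quality decision tree on hand-built feature sets.

Three rules: all waves visible; heart rate within 40-180 bpm; T amplitude
not above R (overridable by a successful discriminator pass). Any shortfall
with a visible R wave demotes to 'conditionally acceptable'.
"""

from ecgsqa import FeatureSet, apply_rules


def features(hr, a_r=0.6, a_t=0.2):
    return FeatureSet(a_rwave=a_r, a_twave=a_t, a_swave=0.3,
                      t_rrint=60.0 / hr, r_rrint_maxmin=1.1,
                      beat_count=12, hr_bpm=hr)


cases = [
    ("all rules pass",        features(60),            dict(R=True, S=True, T=True), False),
    ("S and T not visible",   features(60),            dict(R=True, S=False, T=False), False),
    ("bradycardia (30 bpm)",  features(30),            dict(R=True, S=True, T=True), False),
    ("dominant T, unresolved", features(70, 0.5, 0.6), dict(R=True, S=True, T=True), False),
    ("dominant T, resolved",  features(70, 0.5, 0.6),  dict(R=True, S=True, T=True), True),
]
for name, feats, visible, resolved in cases:
    report = apply_rules(feats, visible, large_t_resolved=resolved)
    print(f"{name:24s} -> {report.category}")
# 'acceptable' needs every rule; a record with only a clear R wave still
# supports RR-interval (heart-rate) analysis, hence 'conditionally_acceptable'.
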