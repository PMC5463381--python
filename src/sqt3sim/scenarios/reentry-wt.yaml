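scenario: reentry-wt
pipeline: reentry2d
variant: WT
geometry: {s2_time_ms: 340, width_mm: 75}
numerics: {horizon_ms: 1500}
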