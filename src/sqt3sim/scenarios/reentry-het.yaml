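# Full-size cross-field re-entry attempt, heterozygous sheet (S2 312 ms)
scenario: reentry-het
pipeline: reentry2d
variant: WT-D172N
geometry: {s2_time_ms: 312, width_mm: 75}
numerics: {horizon_ms: 1500}
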