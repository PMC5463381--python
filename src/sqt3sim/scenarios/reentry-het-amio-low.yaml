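scenario: reentry-het-amio-low
pipeline: reentry2d
variant: WT-D172N
drug: {name: amiodarone, dose_uM: 1.0, mode: verbatim}
geometry: {s2_time_ms: 325, width_mm: 75}
numerics: {horizon_ms: 1500}
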