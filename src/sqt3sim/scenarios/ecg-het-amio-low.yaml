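scenario: ecg-het-amio-low
pipeline: ecg
variant: WT-D172N
drug: {name: amiodarone, dose_uM: 1.0, mode: verbatim}
protocol: {n_beats: 3}
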