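scenario: ecg-hom
pipeline: ecg
variant: D172N
protocol: {n_beats: 3}
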