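# Simulated voltage-clamp I-V relations and peak-current folds
scenario: clamp-iv
pipeline: clamp
variants: [WT, WT-D172N, D172N]
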