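# Planar-wave conduction velocity of the transmural strand
scenario: fiber-cv
pipeline: fiber
variant: WT
protocol: {n_beats: 1}
numerics: {horizon_ms: 150}
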