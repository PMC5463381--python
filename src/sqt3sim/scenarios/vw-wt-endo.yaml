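# Vulnerable window, WT strand, premature stimulus at the ENDO segment
scenario: vw-wt-endo
pipeline: vulnerability
variant: WT
geometry: {s2_site: ENDO, s2_time_ms: 320}
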