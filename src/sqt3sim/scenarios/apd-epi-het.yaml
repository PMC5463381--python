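# APD90 of the heterozygous-variant EPI cell at BCL 800 ms
scenario: apd-epi-het
pipeline: cell
variant: WT-D172N
cell_type: EPI
protocol: {bcl_ms: 800, n_beats: 10}
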