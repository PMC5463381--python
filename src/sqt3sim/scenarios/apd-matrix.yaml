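# APD90 of all three transmural cell types under all three genotypes
scenario: apd-matrix
pipeline: cell
variants: [WT, WT-D172N, D172N]
cell_types: [ENDO, MIDDLE, EPI]
protocol: {bcl_ms: 800, n_beats: 10}
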