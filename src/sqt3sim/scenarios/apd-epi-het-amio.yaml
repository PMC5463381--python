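# Heterozygous EPI cell with low-dose amiodarone (verbatim block table)
scenario: apd-epi-het-amio
pipeline: cell
variant: WT-D172N
cell_type: EPI
drug: {name: amiodarone, dose_uM: 1.0, mode: verbatim}
protocol: {bcl_ms: 800, n_beats: 10}
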