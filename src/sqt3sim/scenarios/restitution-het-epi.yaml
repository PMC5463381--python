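# APD-R and ERP-R curves of the heterozygous EPI cell
scenario: restitution-het-epi
pipeline: restitution
variant: WT-D172N
cell_type: EPI
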