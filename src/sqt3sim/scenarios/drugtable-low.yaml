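# Published conductance percentages at the low therapeutic dose
scenario: drugtable-low
pipeline: drugtable
drug: {name: amiodarone, dose_uM: 1.0, mode: verbatim}
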