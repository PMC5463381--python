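# Pseudo-ECG QT of the heterozygous strand, drug free (beat 3 of BCL 800)
scenario: ecg-het
pipeline: ecg
variant: WT-D172N
protocol: {n_beats: 3}
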