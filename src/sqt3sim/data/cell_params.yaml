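ENDO/D172N:
  ca_o: 2.0
  cell_type: ENDO
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.392
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.073
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 3.171656356562
    shift_mV: 7.5
    slope: 0.088
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: D172N
ENDO/WT:
  ca_o: 2.0
  cell_type: ENDO
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.392
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.073
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 1.0
    shift_mV: 0.0
    slope: 0.1
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: WT
ENDO/WT-D172N:
  ca_o: 2.0
  cell_type: ENDO
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.392
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.073
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 1.601636057687
    shift_mV: 5.0
    slope: 0.08
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: WT-D172N
EPI/D172N:
  ca_o: 2.0
  cell_type: EPI
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.392
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.294
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 3.171656356562
    shift_mV: 7.5
    slope: 0.088
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: D172N
EPI/WT:
  ca_o: 2.0
  cell_type: EPI
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.392
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.294
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 1.0
    shift_mV: 0.0
    slope: 0.1
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: WT
EPI/WT-D172N:
  ca_o: 2.0
  cell_type: EPI
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.392
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.294
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 1.601636057687
    shift_mV: 5.0
    slope: 0.08
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: WT-D172N
MIDDLE/D172N:
  ca_o: 2.0
  cell_type: MIDDLE
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.098
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.294
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 3.171656356562
    shift_mV: 7.5
    slope: 0.088
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: D172N
MIDDLE/WT:
  ca_o: 2.0
  cell_type: MIDDLE
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.098
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.294
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 1.0
    shift_mV: 0.0
    slope: 0.1
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: WT
MIDDLE/WT-D172N:
  ca_o: 2.0
  cell_type: MIDDLE
  cm: 1.0
  g_bca: 0.000592
  g_bna: 0.00029
  g_cal: 3.98e-05
  g_kr: 0.153
  g_ks: 0.098
  g_na: 14.838
  g_nal: 0.0075
  g_pca: 0.1238
  g_pk: 0.0146
  g_to: 0.294
  ik1:
    g_k1: 5.405
    k_o: 5.4
    scale: 1.601636057687
    shift_mV: 5.0
    slope: 0.08
  k_naca: 1000.0
  na_o: 140.0
  p_nak: 2.724
  variant: WT-D172N
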