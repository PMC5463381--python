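drug,dose_uM,conductance,percent_remaining
amiodarone,1,G_Kr,71.28
amiodarone,1,G_Na,76.33
amiodarone,1,P_NaK,93.98
amiodarone,1,G_CaL,85.29
amiodarone,1,P_NaCa,76.74
amiodarone,1,G_Ks,69.42
amiodarone,3,G_Kr,48.41
amiodarone,3,G_Na,58.78
amiodarone,3,P_NaK,83.87
amiodarone,3,G_CaL,65.91
amiodarone,3,P_NaCa,52.38
amiodarone,3,G_Ks,53.73
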