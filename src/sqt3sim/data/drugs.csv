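drug,current,ic50_uM,nh,source
amiodarone,I_Kr,2.80,0.91,Kamiya et al. guinea-pig ventricular myocytes
amiodarone,I_Na,4.84,0.76,Follmer et al. canine ventricular myocytes
amiodarone,I_NaK,15.60,1.00,Gray et al.
amiodarone,I_CaL,5.80,1.00,Nishimura et al.
amiodarone,I_NaCa,3.30,1.00,Watanabe & Kimura
amiodarone,I_Ks,3.84,0.63,Lai et al.
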