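# Calibrated inward-rectifier (I_K1) variant constants.
#
# Written by sqt3sim.clamp_fit.calibrate_variants under the default simulated
# voltage-clamp protocol (holding -60 mV, 400 ms steps, -120..+20 mV in 5 mV
# increments, K_o = 5.4 mM, K_i = 138.3 mM).  For each variant the
# multiplicative scale is solved in closed form so that the peak outward
# current is exactly 2.2-fold (WT-D172N) and 4.6-fold (D172N) the WT peak.
# The rectification-cutoff shift (mV, rightward) and slope (mV^-1; baseline
# 0.1) are design constants of the variant parameterization: they move the
# peak repolarizing current to more positive voltages and widen its voltage
# range, and their magnitudes were fixed by verifying the paced action
# potential durations of the three transmural cell types for each genotype
# (see docs/methods.md).
variants:
  WT:
    scale: 1.0
    shift_mV: 0.0
    slope: 0.1
  WT-D172N:
    scale: 1.601636057687
    shift_mV: 5.0
    slope: 0.08
  D172N:
    scale: 3.171656356562
    shift_mV: 7.5
    slope: 0.088
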