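# Condition effects, expressed in measurement space (ratios of measured
# quantities relative to the untreated control):
#   amplitude_factor  ratio of raw peak values
#   rate_factor       ratio of max 5-min rising slopes
#   peak_shift        additive shift of the peak time, min
#   constrict         whether the actomyosin ring constricts
#   fall_mode         "linear" = disassembly without constriction
#   fast_rate_factor  multiplier on the fast-phase constriction rate
# All numeric factors below are the published measured values for each
# protein under the perturbation.
DMSO: {}
LatA:
  constrict: false
  fall_mode: linear
  effects:
    Myo1: {amplitude_factor: 0.91, peak_shift: 0.0}
    Iqg1: {amplitude_factor: 0.84, peak_shift: -3.0}
    Mlc1: {amplitude_factor: 0.66, peak_shift: -3.0}
    Myo2: {amplitude_factor: 0.53, rate_factor: 0.12, peak_shift: 16.5}
    Chs2: {amplitude_factor: 0.73, rate_factor: 0.37, peak_shift: 15.0}
    Chs3: {amplitude_factor: 0.65, rate_factor: 0.29, peak_shift: 19.5}
    Fks1: {amplitude_factor: 0.05}
cyk3del:
  fast_rate_factor: 0.6
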