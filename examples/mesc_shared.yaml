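# Oct4-like telegraph kinetics in mouse embryonic stem cells, identical in
# both cell-cycle stages; stage durations 560 min (S1) and 220 min (S2).
# Rates are per hour unless tagged otherwise.
stage1:
  lambda: 0.5556
  gamma: 1.0714
  nu: {value: 1.89, unit: per_minute}
  delta: 0.14
stage2:
  lambda: 0.5556
  gamma: 1.0714
  nu: {value: 1.89, unit: per_minute}
  delta: 0.14
cycle:
  kappa1: 0.10714285714285714   # 60/560
  kappa2: 0.2727272727272727    # 60/220
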