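# Stage-resolved Oct4 kinetics: activation drops from 0.5556 to 0.3468 per
# hour across gene duplication; shared synthesis, inactivation, degradation.
stage1: {lambda: 0.5556, gamma: 1.0714, nu: 1.0, delta: 17.14}
stage2: {lambda: 0.3468, gamma: 1.0714, nu: 1.0, delta: 17.14}
cycle: {kappa1: 0.1071, kappa2: 0.2727}
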