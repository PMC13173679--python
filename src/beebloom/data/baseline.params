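# Baseline parameter set for the plant-honeybee-honey model.
r1 = 0.56
k1 = 10
alpha1 = 0.04
w = 3
a = 0.02
b = 0.03
gamma1 = 0.04
r2 = 0.18
k2 = 6
alpha2 = 0.08
gamma2 = 0.03
alpha3 = 0.01
beta = 0.00157
gamma3 = 0.0018
c = 0.01
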