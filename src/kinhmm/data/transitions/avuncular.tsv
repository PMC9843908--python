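# case: avuncular
# r: 1e-08
# b: 10000000
# source: empirical
# seed: 20260922
# n_sims: 1000
8.090212490649197896e-01 1.909787509350801549e-01
1.913593330507277201e-01 8.086406669492722799e-01
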