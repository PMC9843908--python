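# case: fifth_degree
# r: 1e-08
# b: 10000000
# source: empirical
# seed: 20260922
# n_sims: 1000
9.786230575603550585e-01 2.137694243964490329e-02
3.156417862583179579e-01 6.843582137416820421e-01
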