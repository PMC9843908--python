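# case: fourth_degree
# r: 1e-08
# b: 10000000
# source: empirical
# seed: 20260922
# n_sims: 1000
9.587768570206766094e-01 4.122314297932341831e-02
2.851847399214554879e-01 7.148152600785445676e-01
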