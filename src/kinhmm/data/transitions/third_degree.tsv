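# case: third_degree
# r: 1e-08
# b: 10000000
# source: empirical
# seed: 20260922
# n_sims: 1000
9.277108027449459948e-01 7.228919725505403293e-02
2.152531295560806412e-01 7.847468704439193310e-01
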