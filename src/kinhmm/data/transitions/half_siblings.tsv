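# case: half_siblings
# r: 1e-08
# b: 10000000
# source: empirical
# seed: 20260922
# n_sims: 1000
8.365948521625804490e-01 1.634051478374195787e-01
1.601559368235388470e-01 8.398440631764612085e-01
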