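m: 40
n: 60
K: 3
n_informative: 6
active_fraction_range: [0.05, 0.12]
n_bits: 128
n_scaffolds: 10
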