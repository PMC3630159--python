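# Full pipeline on the bundled reference simulation (see README)
simulate: {seed: 42}
n_repeats: 100
mc_samples: 100000
seed: 0
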