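# Cue-induced expectation effects, single-layer filter, discrete trials.
scenario: placebo_nocebo_single
seed: 1
n_individuals: 28
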