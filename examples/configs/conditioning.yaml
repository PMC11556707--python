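# Classical conditioning of cue gains, hierarchical filter.
scenario: conditioning_hier
seed: 1
n_individuals: 28
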