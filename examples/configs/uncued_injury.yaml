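# Damage without a predictive cue (the unexpected-injury variant).
scenario: uncued_injury
seed: 1
n_replicates: 100
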