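# Pain outliving tissue damage under ambiguous sensation.
scenario: chronic_pain
seed: 1
n_replicates: 100
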