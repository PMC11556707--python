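# T1/T2/T3 offset-analgesia paradigm with the adaptive filter.
scenario: offset_analgesia
seed: 1
n_replicates: 100
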