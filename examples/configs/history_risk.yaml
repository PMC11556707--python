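# Pain-history risk factors for post-injury neuropathic pain.
scenario: history_risk
seed: 1
n_replicates: 100
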