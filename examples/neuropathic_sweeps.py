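"""Neuropathic pain as disrupted sensory input (fixed and adaptive models).

Nerve injury is modelled as a step increase of the sensory-noise variance R
while the tissue is actually undamaged (x = 0).  The fixed-parameter sweep
shows that pain then follows the internal model's persistence A_hat; the
adaptive sweep shows what happens when A_hat itself is estimated: moderate
disruption drags A_hat to 1, extreme disruption leaves it a random walk.
"""

from painfilter.scenarios import run_neuropathic_hier_sweep, run_neuropathic_single_sweep

single = run_neuropathic_single_sweep(seed=1, n_replicates=50)
print("fixed internal model -- median pain during sensory disruption:")
for label, value in single.extras["post_injury_median"].items():
    print(f"  {label:22s} {value:6.2f}")

hier = run_neuropathic_hier_sweep(seed=1, n_replicates=50)
print("\nadaptive internal model -- terminal persistence estimate and pain:")
for label in hier.extras["terminal_A_median"]:
    print(
        f"  {label:18s} A_hat -> {hier.extras['terminal_A_median'][label]:5.2f}   "
        f"median pain {hier.extras['post_injury_pain_median'][label]:5.2f}"
    )
print(
    "\nSpontaneous pain without tissue damage needs both: uninformative"
    " sensation AND a persistence estimate at or above 1."
)
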