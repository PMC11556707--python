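"""Offset analgesia: a small stimulus decrease, a large pain drop.

Noxious heat follows the T1 (low) / T2 (high) / T3 (low) paradigm with no
predictive cues; tissue damage is proportional to temperature.  The
adaptive filter raises its persistence estimate during T2, so the T2->T3
decrease produces prediction errors that briefly drive perceived pain
*below* the control condition held at the low temperature throughout.
"""

from painfilter.scenarios import run_offset_analgesia

res = run_offset_analgesia(seed=1)
print(res.cells.round(3).to_string(index=False))
off = res.cells.query("condition == 'offset'").set_index("interval")["median"]
ctl = res.cells.query("condition == 'control'").set_index("interval")["median"]
print(
    f"\nundershoot in T3_1: offset {off['T3_1']:.2f} vs control {ctl['T3_1']:.2f}"
    f" (depth {ctl['T3_1'] - off['T3_1']:.2f}), recovering across"
    f" T3_2..T3_4 toward {off['T3_4']:.2f}."
)
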