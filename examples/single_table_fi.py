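"""Fragility index of single tables, including ones where no FI exists.

The fragility index (FI) asks: in the arm with fewer events, how many
nonevents must flip to events (arm size fixed) before a significant
two-sided Fisher exact result (p < 0.05) becomes nonsignificant? For some
valid tables the answer is "never" — the algorithm either cannot start or
runs out of patients to flip — and the engine reports that explicitly.
"""

from fragility import ContingencyTable, Status, fragility_index

for cells in [(1, 9, 8, 2), (3, 0, 4, 11), (9, 35, 8, 8)]:
    table = ContingencyTable(*cells)
    out = fragility_index(table)
    print(f"table {table}  baseline p = {out.trajectory[0][1]:.4f}" if out.trajectory else table)
    if out.status is Status.ATTAINABLE:
        print(f"  ATTAINABLE: FI = {out.fi} "
              f"(p crosses 0.05 after {out.fi} outcome flip(s))")
    elif out.status is Status.NOT_ATTAINABLE:
        print(f"  NOT ATTAINABLE via {out.mechanism.value}: ", end="")
        if len(out.trajectory) == 1:
            print("the fewer-events arm has zero nonevents, no flip is legal")
        else:
            print(f"all {len(out.trajectory) - 1} flips spent, p never reached 0.05")
        for step, (t, p) in enumerate(out.trajectory):
            print(f"    step {step}: {t}  p = {p:.4f}")
    else:
        print(f"  NOT EVALUABLE ({out.not_evaluable_reason.value})")
    print()
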