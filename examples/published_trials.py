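"""FI nonattainability in published trial tables from the packaged registry.

Each registry entry is a real (or constructed) two-arm binary-outcome
table; the expected status records whether a finite FI exists. Large
trials are affected too: the N = 4,846 adverse-event table below is
baseline-significant (p = 0.016) yet has no fragility index.
"""

from fragility import fragility_index, registry, two_sided_p

for entry in registry():
    out = fragility_index(entry.table)
    p = two_sided_p(entry.table).p_two_sided
    print(f"{entry.name:16s} {str(entry.table):>22s}  N={entry.table.n:<5d} "
          f"p={p:.4f}  -> {out.status.value}"
          + (f" ({out.mechanism.value})" if out.mechanism else ""))
    assert out.status is entry.expected_status
print("\nevery table above is baseline-significant, yet none has a finite FI")
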