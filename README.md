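# fragility

Fragility index (FI) for 2×2 clinical-trial tables, with explicit
attainability semantics — plus the complete-enumeration machinery that
shows how often, and why, the FI fails to exist.

## The problem

For a two-arm trial with a binary outcome, summarized as the table
{a, b, c, d} (a/c events and b/d nonevents in arms A/B), the original FI
is defined by a forced, one-way path:

1. the baseline table must be significant by a two-sided Fisher exact
   test, p < 0.05;
2. identify the arm with fewer events (tables with a = c are excluded:
   the definition provides no tie-break);
3. convert one nonevent to an event in that arm, keeping the arm size
   fixed, and recompute p;
4. the FI is the minimum number of such conversions ("toggles") needed to
   reach p ≥ 0.05.

The catch: this is a *partial* function. Some perfectly valid,
baseline-significant tables admit no finite FI, in exactly two ways:

- **no legal move** — the selected arm has zero nonevents at baseline
  (e.g. {3, 0, 4, 11}, p = 0.0429): the algorithm cannot take a first step;
- **path exhaustion** — toggles exist, but each one drives p *away* from
  the 0.05 boundary, and the arm runs dry (e.g. {9, 35, 8, 8},
  p = 0.0487 → 0.0116 → 0.0039 → … with all 8 nonevents spent).

This package computes the FI where it exists and names the failure
mechanism where it does not — never a generic error — and provides the
enumeration and association tooling to characterize the phenomenon:
every nondegenerate table at each total size N is generated, classified,
and tallied by attainability, mechanism, minimum cell value, and
allocation imbalance.

Audience: biostatisticians and trialists evaluating robustness metrics,
and methodologists studying when threshold-based fragility measures are
well defined.

## Worked example

```python
>>> from fragility import ContingencyTable, fragility_index
>>> out = fragility_index(ContingencyTable(9, 35, 8, 8))
>>> out.status.value, out.mechanism.value
('not_attainable', 'path_exhausted')
>>> [(str(t), round(p, 4)) for t, p in out.trajectory[:3]]
[('{9,35,8,8}', 0.0487), ('{9,35,9,7}', 0.0116), ('{9,35,10,6}', 0.0039)]
```

Arm B has fewer events (8 < 9), so all toggles go there — but each toggle
raises arm B's event rate toward 100%, *widening* the between-arm
disparity, so p moves monotonically away from 0.05 until the arm is
exhausted after 8 toggles. No finite FI exists.

The same is available from the shell, with distinct exit codes
(0 attainable, 3 not attainable, 4 not evaluable):

```sh
$ fragility fi 3 0 4 11
table {3,0,4,11}  N=18
baseline two-sided Fisher p = 0.0429
status: NOT ATTAINABLE (no_legal_move)
   baseline  {3,0,4,11}  p = 0.0429
  no legal move: the selected arm has zero nonevents at baseline
$ fragility enumerate --n-min 2 --n-max 30 --out run/   # Table-style CSVs + JSON
$ fragility batch --in tables.csv --out results.csv
```

Running the enumeration over N = 2..30
(`examples/enumerate_table_space.py`) prints, among others:

```
  N  significant  attainable  unattainable  ties    rate
 17          264         256             0     8    0.0%
 18          324         314             2     8    0.6%
 30         2010        1850           112    48    5.7%
```

Unattainable cases first appear at N = 18 (2 of 316 evaluable tables) and
recur at every larger N; by N = 60 the rate reaches 11.5%. See
`examples/` for single-table walkthroughs, the published-trial registry,
and the imbalance association.

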