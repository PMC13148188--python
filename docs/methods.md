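# Methods

## The fragility-index algorithm

For a 2×2 table {a, b, c, d} (events/nonevents in arm A, events/nonevents
in arm B), the engine implements the original one-way FI definition as a
total function with three outcomes:

- **ATTAINABLE** with FI = k: starting from a baseline-significant table
  (two-sided Fisher p < α, default α = 0.05) and toggling one nonevent to
  an event per step in the arm with fewer baseline events, the p-value
  first reaches p ≥ α after k steps.
- **NOT_ATTAINABLE** with a mechanism: `no_legal_move` when the selected
  arm has zero nonevents at baseline (the path has no first step), or
  `path_exhausted` when toggles existed but the arm's nonevents ran out
  with every visited p < α.
- **NOT_EVALUABLE** with a reason: degenerate margins, baseline p ≥ α, or
  tied event counts (a = c). Ties are excluded rather than broken: the
  original definition specifies "the arm with fewer events" and provides
  no tie rule, and inventing one would change the object under study.

Two deliberate conventions:

- *Arm selection is frozen at baseline.* The {9,35,8,8} trajectory keeps
  toggling arm B even after arm B's event count ties with and then
  exceeds arm A's; re-selecting per step would define a different (and
  better-behaved) metric.
- *Boundary is p ≥ α exactly*; significance requires strict p < α.

Every outcome carries the full toggle trajectory (at most arm-size + 1
entries), so reports and tests can display and verify the path.

### Degenerate endpoint of a path

A toggle path can end at a table whose nonevent column is empty (both b
and d zero). The conditional hypergeometric distribution is then a point
mass and the exact test carries no information; the engine assigns p = 1
(the convention of both R's `fisher.test` and scipy), so such a final
step terminates the path as attainable.

## Fisher exact test

The kernel computes hypergeometric point probabilities in log space from
a cached cumulative log-factorial array (grown amortized; growth never
changes previously returned values) and takes the two-sided p as the sum
of support probabilities ≤ p_obs·(1 + 1e-7). The relative tolerance is
the convention shared by mainstream implementations; it guards against
floating-point ties in the qualification test. For a whole margin
signature (arm sizes + total events) the p-values of every table in the
support are computed in one vectorized pass: the pmf is sorted once, and
each table's p-value is a prefix sum read off by binary search.

p-values are held at full double precision internally; rounding to the
4-decimal presentation happens only in the CLI/report layer.

Exact symmetry: the test is invariant under swapping arms and under
relabeling outcome columns. Because float summation order is not, the
scalar entry points canonicalize each table to the lexicographic minimum
of its four symmetry variants before traversing the support, making the
invariance bit-exact.

### Knife-edge significance decisions

Thirty-six tables in the N = 2–60 space have a two-sided p equal to
*exactly* 1/20 as a rational number. Whether they count as "p < 0.05" is
then decided entirely by last-ulp rounding and differs between
implementations — and even between orientations of the same table within
one implementation. Classification counts should not depend on which
Fisher engine happens to be linked, so decisions within 1e-9 of α are
delegated to a reference convention: a faithful scalar port of R's
`fisher.test` two-sided code path (Loader's saddle-point hypergeometric
density, renormalized conditional pmf, extended-precision sequential
summation), evaluated with the higher-events arm oriented first so the
decision is orientation-free. The port was verified bit-for-bit against
R on every table with N ≤ 22, all knife-edge tables, and thousands of
random tables up to N = 120; a suite test repeats a subset of that check
against Rscript. Away from the window the fast vectorized kernel decides
directly; the two engines agree everywhere except in the last ulp.

## Enumeration

`enumerate_tables(N)` yields each table with a + b + c + d = N passing
the nondegeneracy filters (both arms nonempty, both outcome columns
present) exactly once, in lexicographic (a, b, c) order — counts are
order-invariant, but the fixed order makes record files byte-stable.
`classify_range` walks margin signatures instead of individual tables so
each hypergeometric support is computed once, caches p-vectors keyed by
(row sums, total events), and hands the FI engine a cached-lookup
p-function: a toggle preserves the arm sizes and increments total events
by one, so every path step is a cache hit. The full N = 2–60 run
(296,192 evaluable tables) completes in ~20 s on one CPU.

Per-table records are kept for baseline-significant tables only (what
the tallies and the association need). The per-N summary mirrors the
enumeration bookkeeping: total significant = attainable + unattainable +
ties excluded, and the unattainability rate is
unattainable/(attainable + unattainable), recomputed from the counts and
formatted to one decimal of percent only at presentation time.

## Association

Each evaluable table (attainable or unattainable; tie-excluded and
nonsignificant tables do not enter) is one observation. The outcome is
the 0/1 nonattainability indicator; predictors are allocation imbalance
— the larger-to-smaller arm-size ratio, ≥ 1, so the predictor does not
depend on which arm is labeled A — and total N. Spearman rank
correlation uses midranks for ties (the binary outcome enters the same
rank machinery; no point-biserial shortcut, keeping one code path), with
a 95% CI from the Fisher z-transform, SE = 1/√(n − 3). The z-transform
CI is a standard choice; the quantity is descriptive here, not
inferential.

Over N = 2–60 the imbalance correlation is r = 0.324. The total-N
correlation is r = 0.055: sample size by itself carries little rank
information about whether a given table's FI exists (the per-N *rate*
rises with N, but within the pooled table population N is a weak
per-table discriminator). For reference, the rank correlation between
the two predictors themselves (N vs imbalance) is r = 0.015.

## Random-table generator

`random_tables` draws N uniformly from [2, n_max], then a quadruple
uniformly over all compositions of N into four nonnegative cells via the
cut-point bijection, rejecting degenerate tables — i.e. uniform over the
valid table set at each N, matching the enumeration's population. It
exists for property testing (path-conservation and symmetry invariants
on thousands of tables); it does not emulate trial-design realities
(randomization ratios, event-rate priors), so passing property tests
says the algorithm's invariants hold over the table space, not that any
sampling distribution of published trials is represented. The generator
is a seeded `numpy` Generator; no global RNG state.

## Numerical and edge-case choices

- Log-factorial cache: grown geometrically to the largest N seen
  (the registry's largest table has N = 4,846).
- Two-sided qualification tolerance: relative 1e-7 (see above); boundary
  window for delegating significance decisions: |p − α| < 1e-9.
- Empty inputs: tallies of an empty record list are empty; association
  on records with no evaluable tables, or with a constant outcome
  (e.g. a range with no unattainable tables), raises a domain error
  rather than returning an undefined r.
- CSV I/O: header required; both {a,b,c,d} and
  {events_A,nonevents_A,events_B,nonevents_B} column schemes accepted;
  malformed cells reported with row numbers; integer round-trip exact to
  at least 10^7.
- CLI exit codes: 0 attainable, 3 not attainable, 4 not evaluable,
  2 usage error — nonattainability is a first-class named result a
  script can branch on, never a generic failure.

## Known limitations

- One-sided tests, mid-p corrections, odds-ratio estimation, bidirectional
  or cross-arm toggling variants (global FI, two-arm modification), the
  fragility quotient, and reverse FI for nonsignificant results are out
  of scope.
- The enumeration is exact but finite; no asymptotic claim is made beyond
  the largest N enumerated.
- Tied-event tables are excluded by definition, not resolved; any
  conclusion about them would require a tie-break rule the metric does
  not define.
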