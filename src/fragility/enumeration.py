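"""Complete enumeration of valid 2x2 tables and FI classification.

For each total sample size N, every nondegenerate table {a,b,c,d} with
a+b+c+d = N is generated (both arms nonempty, both outcome columns
present), its baseline two-sided Fisher p computed, and every
baseline-significant table classified by the FI algorithm. Per-N counts
and per-table records feed the summary tables, the mechanism taxonomy,
the minimum-cell tally and the imbalance association.

Performance note: tables sharing margins (arm sizes, total events) share
one hypergeometric support, so p-values are computed vectorized per margin
signature and cached; the FI toggle path preserves arm sizes and only
increments total events, so every path step is a cache hit.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterator, Optional

from .engine import (
    BOUNDARY_WINDOW,
    DEFAULT_ALPHA,
    Evaluability,
    FragilityOutcome,
    Mechanism,
    Status,
    fragility_index,
    is_significant,
)
from .fisher import support_two_sided
from .tables import ContingencyTable


@dataclass(frozen=True, slots=True)
class TableRecord:
    """One baseline-significant table from an enumeration run."""

    table: ContingencyTable
    n_total: int
    p_baseline: float
    evaluability: Evaluability
    outcome: Optional[FragilityOutcome]
    min_cell: int
    imbalance_ratio: float


@dataclass(frozen=True, slots=True)
class EnumSummaryRow:
    """Per-N counts: one row of the enumeration summary table."""

    n_total: int
    total_significant: int
    attainable: int
    unattainable: int
    ties_excluded: int

    @property
    def unattainability_rate(self) -> Optional[float]:
        """unattainable / (attainable + unattainable), None when undefined."""
        denom = self.attainable + self.unattainable
        return self.unattainable / denom if denom else None


def enumerate_tables(n_total: int) -> Iterator[ContingencyTable]:
    """Yield every nondegenerate table with total N, once, in (a,b,c) order.

    Retention: each arm nonempty (a+b > 0, c+d > 0) and each outcome column
    present (a+c > 0, b+d > 0).
    """
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    for a in range(n_total + 1):
        for b in range(n_total - a + 1):
            for c in range(n_total - a - b + 1):
                d = n_total - a - b - c
                if a + b > 0 and c + d > 0 and a + c > 0 and b + d > 0:
                    yield ContingencyTable(a, b, c, d)


class MarginPCache:
    """Cached two-sided p-values keyed by margin signature (arm sizes, events).

    ``lookup`` serves as the p-value function handed to the FI engine, so the
    engine and the enumeration share a single set of Fisher computations.
    """

    def __init__(self) -> None:
        self._cache: dict[tuple[int, int, int], tuple[int, object]] = {}

    def support(self, row_a: int, row_b: int, col_events: int):
        key = (row_a, row_b, col_events)
        hit = self._cache.get(key)
        if hit is None:
            a_min, _, p_two = support_two_sided(row_a, row_b, col_events)
            hit = (a_min, p_two)
            self._cache[key] = hit
        return hit

    def lookup(self, table: ContingencyTable) -> float:
        a_min, p_two = self.support(table.row_a, table.row_b, table.col_events)
        return float(p_two[table.a - a_min])


def classify_tables(
    n_total: int,
    alpha: float = DEFAULT_ALPHA,
    cache: Optional[MarginPCache] = None,
) -> tuple[list[TableRecord], EnumSummaryRow]:
    """Classify every nondegenerate table at one N; keep significant records."""
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    cache = cache or MarginPCache()
    records: list[TableRecord] = []
    n_sig = n_att = n_unatt = n_tied = 0
    # iterate margin signatures; every nondegenerate table appears in exactly one
    for row_a in range(1, n_total):
        row_b = n_total - row_a
        for col_events in range(1, n_total):
            a_min, p_two = cache.support(row_a, row_b, col_events)
            for i, p in enumerate(p_two):
                if p >= alpha and not (p - alpha < BOUNDARY_WINDOW):
                    continue
                a = a_min + i
                c = col_events - a
                table = ContingencyTable(a, row_a - a, c, row_b - c)
                if not is_significant(float(p), table, alpha):
                    continue
                n_sig += 1
                if a == c:
                    n_tied += 1
                    records.append(
                        TableRecord(
                            table=table,
                            n_total=n_total,
                            p_baseline=float(p),
                            evaluability=Evaluability.TIED_EVENTS,
                            outcome=None,
                            min_cell=table.min_cell,
                            imbalance_ratio=table.imbalance_ratio,
                        )
                    )
                    continue
                outcome = fragility_index(table, alpha=alpha, p_func=cache.lookup)
                if outcome.status is Status.ATTAINABLE:
                    n_att += 1
                else:
                    n_unatt += 1
                records.append(
                    TableRecord(
                        table=table,
                        n_total=n_total,
                        p_baseline=float(p),
                        evaluability=Evaluability.EVALUABLE,
                        outcome=outcome,
                        min_cell=table.min_cell,
                        imbalance_ratio=table.imbalance_ratio,
                    )
                )
    records.sort(key=lambda r: r.table.cells())
    summary = EnumSummaryRow(
        n_total=n_total,
        total_significant=n_sig,
        attainable=n_att,
        unattainable=n_unatt,
        ties_excluded=n_tied,
    )
    return records, summary


def classify_range(
    n_min: int,
    n_max: int,
    alpha: float = DEFAULT_ALPHA,
    progress: Optional[Callable[[EnumSummaryRow], None]] = None,
) -> tuple[list[TableRecord], list[EnumSummaryRow]]:
    """Enumerate and classify all nondegenerate tables for N in [n_min, n_max].

    Returns the per-table records of every baseline-significant table
    (ordered by N then lexicographically by cells) and one summary row per N.
    ``progress``, if given, is called with each completed summary row.
    """
    if not (2 <= n_min <= n_max):
        raise ValueError(f"need 2 <= n_min <= n_max, got n_min={n_min}, n_max={n_max}")
    records: list[TableRecord] = []
    summaries: list[EnumSummaryRow] = []
    for n_total in range(n_min, n_max + 1):
        recs, row = classify_tables(n_total, alpha=alpha)
        records.extend(recs)
        summaries.append(row)
        if progress is not None:
            progress(row)
    return records, summaries


def _unattainable(records: list[TableRecord]) -> Iterator[TableRecord]:
    for r in records:
        if r.outcome is not None and r.outcome.status is Status.NOT_ATTAINABLE:
            yield r


def min_cell_tally(records: list[TableRecord]) -> Counter:
    """Minimum-cell-value frequencies among unattainable tables."""
    return Counter(r.min_cell for r in _unattainable(records))


def mechanism_tally(records: list[TableRecord]) -> Counter:
    """Counts of the two nonattainability mechanisms among unattainable tables."""
    return Counter(r.outcome.mechanism for r in _unattainable(records))


SUMMARY_HEADER = [
    "n_total",
    "total_significant",
    "fi_attainable",
    "fi_unattainable",
    "ties_excluded",
    "unattainability_rate",
]

RECORDS_HEADER = [
    "a", "b", "c", "d", "n_total", "p_baseline",
    "status", "mechanism", "fi", "min_cell", "imbalance_ratio",
]


def write_summary_csv(summaries: list[EnumSummaryRow], path) -> None:
    """Per-N summary CSV; the rate column carries one decimal of percent."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SUMMARY_HEADER)
        for row in summaries:
            rate = row.unattainability_rate
            w.writerow(
                [
                    row.n_total,
                    row.total_significant,
                    row.attainable,
                    row.unattainable,
                    row.ties_excluded,
                    "" if rate is None else f"{100 * rate:.1f}%",
                ]
            )


def write_records_csv(records: list[TableRecord], path) -> None:
    """Per-table records CSV for baseline-significant tables."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RECORDS_HEADER)
        for r in records:
            if r.evaluability is Evaluability.TIED_EVENTS:
                status, mech, fi = "tied_excluded", "", ""
            else:
                status = r.outcome.status.value
                mech = r.outcome.mechanism.value if r.outcome.mechanism else ""
                fi = r.outcome.fi if r.outcome.fi is not None else ""
            w.writerow(
                [
                    *r.table.cells(),
                    r.n_total,
                    f"{r.p_baseline:.17g}",
                    status,
                    mech,
                    fi,
                    r.min_cell,
                    f"{r.imbalance_ratio:.17g}",
                ]
            )


def read_records_csv(path) -> list[TableRecord]:
    """Read back a per-table records CSV written by :func:`write_records_csv`.

    Outcome trajectories are not stored in the CSV; reconstructed records
    carry a trajectory-free outcome sufficient for tallies and association.
    """
    records: list[TableRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [k for k in RECORDS_HEADER if k not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"records CSV missing columns: {missing}")
        for row in reader:
            table = ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
            status = row["status"]
            if status == "tied_excluded":
                ev, outcome = Evaluability.TIED_EVENTS, None
            else:
                ev = Evaluability.EVALUABLE
                st = Status(status)
                outcome = FragilityOutcome(
                    status=st,
                    fi=int(row["fi"]) if row["fi"] else None,
                    mechanism=Mechanism(row["mechanism"]) if row["mechanism"] else None,
                )
            records.append(
                TableRecord(
                    table=table,
                    n_total=int(row["n_total"]),
                    p_baseline=float(row["p_baseline"]),
                    evaluability=ev,
                    outcome=outcome,
                    min_cell=int(row["min_cell"]),
                    imbalance_ratio=float(row["imbalance_ratio"]),
                )
            )
    return records
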