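"""Named reference tables, CSV batch I/O and a seeded random-table generator.

The registry ships the constructed nonattainability counterexamples and the
published-trial tables used throughout the documentation and tests; the CSV
reader/writer supports batch evaluation of user-supplied tables; the random
generator samples nondegenerate tables uniformly for property testing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import numpy as np

from .engine import Status
from .tables import ContingencyTable

# Both column-name schemes accepted in user CSVs.
_SHORT_COLS = ("a", "b", "c", "d")
_LONG_COLS = ("events_A", "nonevents_A", "events_B", "nonevents_B")


@dataclass(frozen=True, slots=True)
class NamedTable:
    """A reference table with provenance and, where known, expected status."""

    name: str
    table: ContingencyTable
    expected_status: Optional[Status]
    note: str


def registry() -> list[NamedTable]:
    """The packaged registry of counterexample and published-trial tables."""
    text = resources.files("fragility").joinpath("data/registry.csv").read_text()
    out: list[NamedTable] = []
    seen: set[str] = set()
    for row in csv.DictReader(text.splitlines()):
        name = row["name"]
        if name in seen:
            raise ValueError(f"duplicate registry name: {name}")
        seen.add(name)
        out.append(
            NamedTable(
                name=name,
                table=ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"])),
                expected_status=Status(row["expected_status"]) if row["expected_status"] else None,
                note=row["note"],
            )
        )
    return out


def _resolve_columns(fieldnames: list[str]) -> tuple[str, str, str, str]:
    for scheme in (_SHORT_COLS, _LONG_COLS):
        if all(c in fieldnames for c in scheme):
            return scheme
    raise ValueError(
        f"CSV must contain columns {_SHORT_COLS} or {_LONG_COLS}; found {fieldnames}"
    )


def read_tables_csv(path) -> list[tuple[str, ContingencyTable]]:
    """Read (identifier, table) pairs from a CSV file.

    Accepts either ``a,b,c,d`` or ``events_A,nonevents_A,events_B,nonevents_B``
    columns plus an optional ``id`` column (row number used otherwise).
    Malformed cells are reported with their row numbers.
    """
    out: list[tuple[str, ContingencyTable]] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty CSV, header required")
        cols = _resolve_columns(list(reader.fieldnames))
        for lineno, row in enumerate(reader, start=2):
            ident = row.get("id") or f"row{lineno}"
            try:
                cells = []
                for c in cols:
                    raw = (row[c] or "").strip()
                    if not raw.lstrip("-").isdigit():
                        raise ValueError(f"cell {c}={raw!r} is not an integer")
                    cells.append(int(raw))
                out.append((ident, ContingencyTable(*cells)))
            except (ValueError, TypeError) as exc:
                errors.append(f"row {lineno} ({ident}): {exc}")
    if errors:
        raise ValueError("invalid rows in " + str(path) + ":\n  " + "\n  ".join(errors))
    return out


def write_tables_csv(pairs: Iterable[tuple[str, ContingencyTable]], path) -> None:
    """Write (identifier, table) pairs; round-trips exactly with the reader."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", *_SHORT_COLS])
        for ident, t in pairs:
            w.writerow([ident, *t.cells()])


def random_tables(n_tables: int, n_total_max: int, seed: int) -> list[ContingencyTable]:
    """Seeded sample of nondegenerate tables, uniform over valid quadruples.

    N is drawn uniformly from [2, n_total_max]; given N, the quadruple is
    uniform over all compositions of N into four nonnegative cells, with
    degenerate tables (empty arm or absent outcome column) rejected.
    Identical seeds produce identical lists.
    """
    if n_tables < 1:
        raise ValueError(f"n_tables must be >= 1, got {n_tables}")
    if n_total_max < 2:
        raise ValueError(f"n_total_max must be >= 2, got {n_total_max}")
    rng = np.random.default_rng(seed)
    out: list[ContingencyTable] = []
    while len(out) < n_tables:
        n = int(rng.integers(2, n_total_max + 1))
        # uniform composition of n into 4 parts via the cut-point bijection
        cuts = np.sort(rng.choice(n + 3, size=3, replace=False))
        a = int(cuts[0])
        b = int(cuts[1] - cuts[0] - 1)
        c = int(cuts[2] - cuts[1] - 1)
        d = int(n + 2 - cuts[2])
        if a + b > 0 and c + d > 0 and a + c > 0 and b + d > 0:
            out.append(ContingencyTable(a, b, c, d))
    return out
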