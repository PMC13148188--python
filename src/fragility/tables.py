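"""2x2 contingency tables for two-arm binary-outcome trials.

The four cells follow the standard nomenclature {a, b, c, d}: ``a`` events
and ``b`` nonevents in arm A, ``c`` events and ``d`` nonevents in arm B.
"""

from __future__ import annotations

from dataclasses import dataclass


class DegenerateTableError(ValueError):
    """A required margin (arm or outcome column) of the table is empty."""


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """A 2x2 table of nonnegative integer cell counts.

    Parameters
    ----------
    a, b : int
        Events and nonevents in arm A.
    c, d : int
        Events and nonevents in arm B.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, int):
                # numpy integers are fine; coerce them so cells stay plain ints
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise TypeError(f"cell {name} must be an integer, got {v!r}")
                if iv != v:
                    raise TypeError(f"cell {name} must be an integer, got {v!r}")
                object.__setattr__(self, name, iv)
                v = iv
            if v < 0:
                raise ValueError(f"cell {name} must be nonnegative, got {v}")
        if self.n == 0:
            raise ValueError("table must contain at least one subject")

    @property
    def n(self) -> int:
        """Total sample size N = a + b + c + d."""
        return self.a + self.b + self.c + self.d

    @property
    def row_a(self) -> int:
        """Arm A size (a + b)."""
        return self.a + self.b

    @property
    def row_b(self) -> int:
        """Arm B size (c + d)."""
        return self.c + self.d

    @property
    def col_events(self) -> int:
        """Total events (a + c)."""
        return self.a + self.c

    @property
    def col_nonevents(self) -> int:
        """Total nonevents (b + d)."""
        return self.b + self.d

    @property
    def min_cell(self) -> int:
        """Smallest of the four cells."""
        return min(self.a, self.b, self.c, self.d)

    @property
    def imbalance_ratio(self) -> float:
        """Allocation imbalance: larger arm size over smaller arm size (>= 1)."""
        r1, r2 = self.row_a, self.row_b
        if min(r1, r2) == 0:
            raise DegenerateTableError("imbalance ratio undefined: one arm is empty")
        return max(r1, r2) / min(r1, r2)

    def is_degenerate(self) -> bool:
        """True if either arm is empty or either outcome column is absent."""
        return min(self.row_a, self.row_b, self.col_events, self.col_nonevents) == 0

    def require_nondegenerate(self) -> None:
        """Raise :class:`DegenerateTableError` naming the first empty margin."""
        if self.row_a == 0:
            raise DegenerateTableError("arm A is empty (a + b = 0)")
        if self.row_b == 0:
            raise DegenerateTableError("arm B is empty (c + d = 0)")
        if self.col_events == 0:
            raise DegenerateTableError("event column is empty (a + c = 0)")
        if self.col_nonevents == 0:
            raise DegenerateTableError("nonevent column is empty (b + d = 0)")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def __str__(self) -> str:
        return f"{{{self.a},{self.b},{self.c},{self.d}}}"
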