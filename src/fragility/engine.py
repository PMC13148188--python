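"""The original fragility-index algorithm with explicit attainability semantics.

The fragility index (FI) of a baseline-significant 2x2 table is the minimum
number of nonevent-to-event conversions ("toggles") in the arm with fewer
events, arm sizes fixed, needed to push the two-sided Fisher exact p-value
to or above the significance level. The toggle path is forced: the arm is
chosen once at baseline and toggled repeatedly. For some valid tables no
finite FI exists; this module classifies those outcomes instead of failing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional

from .fisher import two_sided_p
from .fisher_ref import two_sided_p_ref
from .tables import ContingencyTable

DEFAULT_ALPHA = 0.05

# Window around alpha inside which a significance decision is a last-ulp
# coin toss; such cases are resolved by the reference-convention p-value
# (see fisher_ref) so classifications are implementation-independent.
BOUNDARY_WINDOW = 1e-9


def is_significant(p: float, table: ContingencyTable, alpha: float = DEFAULT_ALPHA) -> bool:
    """Strict p < alpha, with knife-edge cases resolved by the reference port.

    Tables whose exact two-sided p equals alpha as a rational number (e.g.
    exactly 1/20 at alpha = 0.05) land on one side or the other purely by
    floating-point rounding; the reference convention decides those, with
    the table oriented so the arm with more events comes first (last-ulp
    rounding is orientation-dependent, so the convention must fix one).
    """
    if abs(p - alpha) < BOUNDARY_WINDOW:
        if table.c > table.a:
            table = ContingencyTable(table.c, table.d, table.a, table.b)
        return two_sided_p_ref(table) < alpha
    return p < alpha


class Evaluability(enum.Enum):
    """Whether the FI algorithm applies to a table at all."""

    EVALUABLE = "evaluable"
    NOT_SIGNIFICANT = "not_significant"
    TIED_EVENTS = "tied_events"
    DEGENERATE = "degenerate"


class Arm(enum.Enum):
    """Arm selected for toggling: the arm with fewer events at baseline."""

    ARM_A = "A"
    ARM_B = "B"
    TIED = "tied"


class Status(enum.Enum):
    ATTAINABLE = "attainable"
    NOT_ATTAINABLE = "not_attainable"
    NOT_EVALUABLE = "not_evaluable"


class Mechanism(enum.Enum):
    """Why a NOT_ATTAINABLE outcome arose.

    NO_LEGAL_MOVE: the selected arm has zero nonevents at baseline, so the
    algorithm cannot begin. PATH_EXHAUSTED: toggles were available but the
    p-value never reached the nonsignificance boundary before the arm's
    nonevents ran out.
    """

    NO_LEGAL_MOVE = "no_legal_move"
    PATH_EXHAUSTED = "path_exhausted"


class NoLegalMoveError(ValueError):
    """The selected arm has no nonevents left to toggle."""


@dataclass(frozen=True, slots=True)
class FragilityOutcome:
    """Result of the FI algorithm on one table.

    ``fi`` is present iff status is ATTAINABLE; ``mechanism`` iff
    NOT_ATTAINABLE; ``not_evaluable_reason`` iff NOT_EVALUABLE. The
    trajectory lists every table visited, starting at baseline, paired with
    its two-sided Fisher p-value (empty for non-evaluable inputs).
    """

    status: Status
    fi: Optional[int] = None
    mechanism: Optional[Mechanism] = None
    not_evaluable_reason: Optional[Evaluability] = None
    trajectory: tuple[tuple[ContingencyTable, float], ...] = ()


def evaluability(
    table: ContingencyTable,
    alpha: float = DEFAULT_ALPHA,
    p_func: Optional[Callable[[ContingencyTable], float]] = None,
) -> Evaluability:
    """Classify a table's eligibility for the FI algorithm.

    DEGENERATE if any margin is empty; else NOT_SIGNIFICANT if the baseline
    two-sided Fisher p is >= alpha; else TIED_EVENTS if event counts are
    tied (a == c, for which the arm-selection rule is undefined); else
    EVALUABLE. Total over all tables: never raises.
    """
    if table.is_degenerate():
        return Evaluability.DEGENERATE
    p = (p_func or _default_p)(table)
    if not is_significant(p, table, alpha):
        return Evaluability.NOT_SIGNIFICANT
    if table.a == table.c:
        return Evaluability.TIED_EVENTS
    return Evaluability.EVALUABLE


def select_arm(table: ContingencyTable) -> Arm:
    """The arm with fewer events at baseline (TIED when a == c).

    Selection is made once at baseline and never re-evaluated along the
    toggle path, even if toggling overtakes the other arm's event count.
    """
    if table.a < table.c:
        return Arm.ARM_A
    if table.c < table.a:
        return Arm.ARM_B
    return Arm.TIED


def toggle(table: ContingencyTable, arm: Arm) -> ContingencyTable:
    """Convert one nonevent to an event in the selected arm, arm total fixed."""
    if arm is Arm.ARM_A:
        if table.b == 0:
            raise NoLegalMoveError("arm A has zero nonevents; no legal toggle")
        return ContingencyTable(table.a + 1, table.b - 1, table.c, table.d)
    if arm is Arm.ARM_B:
        if table.d == 0:
            raise NoLegalMoveError("arm B has zero nonevents; no legal toggle")
        return ContingencyTable(table.a, table.b, table.c + 1, table.d - 1)
    raise ValueError("cannot toggle a tied-arm selection")


def _default_p(table: ContingencyTable) -> float:
    return two_sided_p(table).p_two_sided


def _path_p(table: ContingencyTable, p_func: Callable[[ContingencyTable], float]) -> float:
    # The forced path can end at an all-events table (both nonevent cells
    # zero). The conditional distribution is then a point mass: p = 1.
    if table.col_nonevents == 0:
        return 1.0
    return p_func(table)


def fragility_index(
    table: ContingencyTable,
    alpha: float = DEFAULT_ALPHA,
    p_func: Optional[Callable[[ContingencyTable], float]] = None,
) -> FragilityOutcome:
    """Run the original FI algorithm, classifying attainability.

    Walks the unique forced path: select the arm with fewer events at
    baseline, toggle one nonevent to an event in that arm, recompute the
    two-sided Fisher p after each step, and stop at the first p >= alpha
    (ATTAINABLE, FI = number of toggles) or when the arm's nonevents are
    exhausted (NOT_ATTAINABLE). Total function: non-evaluable inputs yield
    a NOT_EVALUABLE outcome rather than an error.

    ``p_func`` optionally replaces the p-value engine (e.g. with a cached
    lookup during enumeration); results are identical by construction.
    """
    p_func = p_func or _default_p
    ev = evaluability(table, alpha=alpha, p_func=p_func)
    if ev is not Evaluability.EVALUABLE:
        return FragilityOutcome(status=Status.NOT_EVALUABLE, not_evaluable_reason=ev)

    arm = select_arm(table)
    p0 = p_func(table)
    trajectory: list[tuple[ContingencyTable, float]] = [(table, p0)]
    current = table
    steps = 0
    while True:
        try:
            current = toggle(current, arm)
        except NoLegalMoveError:
            mech = Mechanism.NO_LEGAL_MOVE if steps == 0 else Mechanism.PATH_EXHAUSTED
            return FragilityOutcome(
                status=Status.NOT_ATTAINABLE, mechanism=mech, trajectory=tuple(trajectory)
            )
        steps += 1
        p = _path_p(current, p_func)
        trajectory.append((current, p))
        if current.col_nonevents == 0 or not is_significant(p, current, alpha):
            return FragilityOutcome(
                status=Status.ATTAINABLE, fi=steps, trajectory=tuple(trajectory)
            )
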