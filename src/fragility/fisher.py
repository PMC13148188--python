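"""Two-sided Fisher exact test for 2x2 tables.

The p-value engine used by every other module. Point probabilities come
from the hypergeometric distribution, computed in log space from a cached
cumulative log-factorial array; the two-sided p-value is the sum of point
probabilities, over all tables sharing the observed margins, that do not
exceed the observed table's point probability (up to a small relative
tolerance guarding against floating-point ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import ContingencyTable, DegenerateTableError

# Relative tolerance in the two-sided qualification test: a support table
# qualifies when its point probability is <= p_obs * (1 + REL_TOL). The
# common convention of mainstream exact-test implementations.
REL_TOL = 1e-7

# Growable cumulative log-factorial cache: _LOGFACT[k] = log(k!).
_LOGFACT = np.zeros(1)


def _logfact(n_max: int) -> np.ndarray:
    """Return the log-factorial array covering 0..n_max, growing the cache."""
    global _LOGFACT
    if n_max >= _LOGFACT.size:
        new_size = max(n_max + 1, 2 * _LOGFACT.size)
        grown = np.empty(new_size)
        old = _LOGFACT.size
        grown[:old] = _LOGFACT
        grown[old:] = np.log(np.arange(old, new_size))
        np.cumsum(grown[old:], out=grown[old:])
        grown[old:] += _LOGFACT[old - 1]
        _LOGFACT = grown
    return _LOGFACT


@dataclass(frozen=True, slots=True)
class FisherResult:
    """Two-sided exact p-value and the observed table's point probability."""

    p_two_sided: float
    p_point: float


def support_probabilities(row_a: int, row_b: int, col_events: int) -> tuple[int, np.ndarray]:
    """Hypergeometric point probabilities over the support of fixed margins.

    Returns ``(a_min, pmf)`` where ``pmf[i]`` is the probability of the table
    with ``a = a_min + i`` events in arm A, conditional on arm sizes
    ``row_a``, ``row_b`` and total events ``col_events``.
    """
    n = row_a + row_b
    a_min = max(0, col_events - row_b)
    a_max = min(row_a, col_events)
    lf = _logfact(n)
    a = np.arange(a_min, a_max + 1)
    c = col_events - a
    logpmf = (
        lf[row_a] - lf[a] - lf[row_a - a]
        + lf[row_b] - lf[c] - lf[row_b - c]
        - (lf[n] - lf[col_events] - lf[n - col_events])
    )
    return a_min, np.exp(logpmf)


def support_two_sided(row_a: int, row_b: int, col_events: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Two-sided p-values for every table in the support of fixed margins.

    Returns ``(a_min, pmf, p_two)`` with ``p_two[i]`` the two-sided Fisher
    p-value of the table with ``a = a_min + i``. Vectorized: the pmf is
    sorted once and each table's p-value is a prefix sum of qualifying
    point probabilities.
    """
    a_min, pmf = support_probabilities(row_a, row_b, col_events)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + REL_TOL), side="right")
    p_two = np.minimum(csum[idx - 1], 1.0)
    return a_min, pmf, p_two


def _canonical(table: ContingencyTable) -> ContingencyTable:
    """Canonical representative under arm and outcome-column swaps.

    The test is exactly invariant under swapping the arms or relabeling the
    outcome columns, but floating-point summation order is not; traversing
    one canonical support per symmetry orbit makes the invariance exact.
    """
    a, b, c, d = table.cells()
    cells = min([(a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a)])
    return table if cells == (a, b, c, d) else ContingencyTable(*cells)


def point_probability(table: ContingencyTable) -> float:
    """Hypergeometric probability of the observed table given its margins.

    ``C(a+b, a) * C(c+d, c) / C(N, a+c)``, computed in log space.
    """
    table.require_nondegenerate()
    table = _canonical(table)
    a_min, pmf = support_probabilities(table.row_a, table.row_b, table.col_events)
    return float(pmf[table.a - a_min])


def two_sided_p(table: ContingencyTable) -> FisherResult:
    """Two-sided Fisher exact test of the observed table.

    Raises :class:`DegenerateTableError` if an arm or outcome column is
    empty; for such tables the conditional distribution is a point mass and
    the test carries no information.
    """
    table.require_nondegenerate()
    table = _canonical(table)
    a_min, pmf, p_two = support_two_sided(table.row_a, table.row_b, table.col_events)
    i = table.a - a_min
    return FisherResult(p_two_sided=float(p_two[i]), p_point=float(pmf[i]))
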