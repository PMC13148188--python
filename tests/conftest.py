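from fractions import Fraction
from math import comb

import pytest

from fragility.tables import ContingencyTable


def exact_point_probability(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact hypergeometric point probability by binomial-coefficient arithmetic."""
    n = a + b + c + d
    return Fraction(comb(a + b, a) * comb(c + d, c), comb(n, a + c))


def exact_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p: enumerate the support, sum qualifying pmfs."""
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(r1, k)
    pmf = {x: exact_point_probability(x, r1 - x, k - x, r2 - (k - x)) for x in range(lo, hi + 1)}
    observed = pmf[a]
    return sum(v for v in pmf.values() if v <= observed)


def all_nondegenerate(n_total: int):
    """Brute-force generator of nondegenerate tables, independent of the package."""
    for a in range(n_total + 1):
        for b in range(n_total - a + 1):
            for c in range(n_total - a - b + 1):
                d = n_total - a - b - c
                if a + b > 0 and c + d > 0 and a + c > 0 and b + d > 0:
                    yield (a, b, c, d)


@pytest.fixture
def counterexample_no_move():
    return ContingencyTable(3, 0, 4, 11)


@pytest.fixture
def counterexample_exhausted():
    return ContingencyTable(9, 35, 8, 8)
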