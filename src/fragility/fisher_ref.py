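"""Reference-convention two-sided Fisher p-value (R ``fisher.test`` port).

A handful of 2x2 tables have a two-sided exact p equal to exactly 1/20 as
a rational number; whether they count as significant at alpha = 0.05 then
depends entirely on last-ulp floating-point rounding, which differs
between implementations and even between orientations of the same table.
The enumeration results this package reproduces follow the convention of
R's ``fisher.test``, so this module provides a faithful scalar port of
that code path: Catherine Loader's saddle-point hypergeometric density
(``dhyper``), the renormalized conditional pmf, the 1 + 1e-7 relative-
tolerance qualification test, and extended-precision sequential summation
(matching R's long-double accumulator).

It is consulted only to decide significance when a p-value falls within a
hair of the threshold; the fast vectorized engine in :mod:`.fisher`
reports p-values everywhere.
"""

from __future__ import annotations

import math

import numpy as np

from .tables import ContingencyTable

_M_LN_SQRT_2PI = 0.918938533204672741780329736406
_M_LN_2PI = 1.837877066409345483560659472811
_DBL_MIN = 2.2250738585072014e-308

_S0 = 0.083333333333333333333  # 1/12
_S1 = 0.00277777777777777777778  # 1/360
_S2 = 0.00079365079365079365079365  # 1/1260
_S3 = 0.000595238095238095238095238  # 1/1680
_S4 = 0.0008417508417508417508417508  # 1/1188

# stirlerr(n) = log(n!) - log(sqrt(2*pi*n)*(n/e)^n) for n = 0.0, 0.5, ..., 15.0,
# each rounded to the nearest double
_SFERR_HALVES = (
    0.0,
    0.15342640972002736,
    0.08106146679532726,
    0.05481412105191765,
    0.0413406959554093,
    0.03316287351993629,
    0.02767792568499834,
    0.023746163656297496,
    0.020790672103765093,
    0.018488450532673187,
    0.016644691189821193,
    0.015134973221917378,
    0.013876128823070748,
    0.012810465242920227,
    0.01189670994589177,
    0.011104559758206917,
    0.010411265261972096,
    0.009799416126158804,
    0.009255462182712733,
    0.008768700134139386,
    0.00833056343336287,
    0.00793411456431402,
    0.007573675487951841,
    0.007244554301320383,
    0.00694284010720953,
    0.006665247032707682,
    0.006408994188004207,
    0.006171712263039458,
    0.0059513701127588475,
    0.0057462165130101155,
    0.005554733551962801,
)


def _stirlerr(n: float) -> float:
    if n <= 15.0:
        nn = n + n
        if nn == int(nn):
            return _SFERR_HALVES[int(nn)]
        return math.lgamma(n + 1.0) - (n + 0.5) * math.log(n) + n - _M_LN_SQRT_2PI
    nn = n * n
    if n > 500.0:
        return (_S0 - _S1 / nn) / n
    if n > 80.0:
        return (_S0 - (_S1 - _S2 / nn) / nn) / n
    if n > 35.0:
        return (_S0 - (_S1 - (_S2 - _S3 / nn) / nn) / nn) / n
    return (_S0 - (_S1 - (_S2 - (_S3 - _S4 / nn) / nn) / nn) / nn) / n


def _bd0(x: float, np_: float) -> float:
    """Deviance term x*log(x/np) + np - x, evaluated stably near x = np."""
    if abs(x - np_) < 0.1 * (x + np_):
        v = (x - np_) / (x + np_)
        s = (x - np_) * v
        if abs(s) < _DBL_MIN:
            return s
        ej = 2.0 * x * v
        v = v * v
        j = 1
        while True:
            ej *= v
            s1 = s + ej / (2 * j + 1)
            if s1 == s:
                return s1
            s = s1
            j += 1
    return x * math.log(x / np_) + np_ - x


def _dbinom_raw_log(x: float, n: float, p: float, q: float) -> float:
    """log of Loader's saddle-point binomial density (R ``dbinom_raw``)."""
    if p == 0.0:
        return 0.0 if x == 0 else -math.inf
    if q == 0.0:
        return 0.0 if x == n else -math.inf
    if x == 0:
        if n == 0:
            return 0.0
        return -_bd0(n, n * q) - n * p if p < 0.1 else n * math.log(q)
    if x == n:
        return -_bd0(n, n * p) - n * q if q < 0.1 else n * math.log(p)
    lc = _stirlerr(n) - _stirlerr(x) - _stirlerr(n - x) - _bd0(x, n * p) - _bd0(n - x, n * q)
    lf = _M_LN_2PI + math.log(x) + math.log1p(-x / n)
    return lc - 0.5 * lf


def _dhyper_log(x: int, r: int, b: int, n: int) -> float:
    """log hypergeometric density: x white from r white, b black, n drawn."""
    if x < 0 or x > r or n - x > b or n - x < 0:
        return -math.inf
    if n == 0:
        return 0.0 if x == 0 else -math.inf
    p = float(n) / float(r + b)
    q = float(r + b - n) / float(r + b)
    p1 = _dbinom_raw_log(float(x), float(r), p, q)
    p2 = _dbinom_raw_log(float(n - x), float(b), p, q)
    p3 = _dbinom_raw_log(float(n), float(r + b), p, q)
    return p1 + p2 - p3


def _lsum(values) -> float:
    """Sequential sum with an extended-precision accumulator (R's sum())."""
    acc = np.longdouble(0.0)
    for v in values:
        acc += np.longdouble(v)
    return float(acc)


def two_sided_p_ref(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p, following R ``fisher.test`` bit-for-bit.

    The conditional pmf over the support is computed from the log density,
    shifted by its maximum, renormalized, and summed over tables whose
    probability does not exceed the observed one times (1 + 1e-7).
    """
    table.require_nondegenerate()
    # parametrized by column margins, mirroring the reference implementation:
    # m successes (events), n2 failures (nonevents), k drawn (arm A size)
    m = table.col_events
    n2 = table.col_nonevents
    k = table.row_a
    lo = max(0, k - n2)
    hi = min(k, m)
    logdc = [_dhyper_log(x, m, n2, k) for x in range(lo, hi + 1)]
    dmax = max(logdc)
    d = [math.exp(v - dmax) for v in logdc]
    total = _lsum(d)
    d = [v / total for v in d]
    d_obs = d[table.a - lo]
    rel_err = 1 + 1e-7
    thresh = d_obs * rel_err
    # the reference implementation does not clamp: ties across the support
    # can push the sum a last ulp above 1
    return _lsum(v for v in d if v <= thresh)
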