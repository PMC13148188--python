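"""Spearman rank correlations between nonattainability and its predictors.

Each enumerated evaluable table is one unit of analysis; the outcome is
the binary nonattainability indicator and the predictors are allocation
imbalance (larger-to-smaller arm-size ratio) and total sample size.
Confidence intervals use the Fisher z-transform with standard error
1/sqrt(n - 3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .engine import Status
from .enumeration import TableRecord


@dataclass(frozen=True, slots=True)
class AssociationResult:
    """Spearman r with a Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self, predictor: str) -> dict:
        return {
            "predictor": predictor,
            "r": self.r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
        }


def spearman_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> AssociationResult:
    """Spearman rank correlation (midrank ties) with a Fisher-z CI.

    Raises ValueError on length mismatch, n < 4, or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-d of equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined: one input vector is constant")
    r = float(stats.spearmanr(x, y).statistic)
    z = math.atanh(max(-1.0 + 1e-15, min(1.0 - 1e-15, r)))
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    return AssociationResult(
        r=r,
        ci_low=math.tanh(z - zcrit * se),
        ci_high=math.tanh(z + zcrit * se),
        n=n,
    )


def predictor_correlations(
    records: Sequence[TableRecord], confidence: float = 0.95
) -> tuple[AssociationResult, AssociationResult]:
    """Correlate nonattainability with imbalance and with total sample size.

    Only evaluable tables (attainable or unattainable; ties and
    non-significant tables excluded) enter. Returns the imbalance result
    first, then the sample-size result.
    """
    evaluable = [r for r in records if r.outcome is not None]
    if not evaluable:
        raise ValueError("no evaluable records: run the enumeration first")
    y = np.fromiter(
        (1.0 if r.outcome.status is Status.NOT_ATTAINABLE else 0.0 for r in evaluable),
        dtype=float,
        count=len(evaluable),
    )
    imbalance = np.fromiter((r.imbalance_ratio for r in evaluable), dtype=float, count=len(evaluable))
    n_total = np.fromiter((r.n_total for r in evaluable), dtype=float, count=len(evaluable))
    return (
        spearman_with_ci(imbalance, y, confidence=confidence),
        spearman_with_ci(n_total, y, confidence=confidence),
    )


def write_association_json(
    results: tuple[AssociationResult, AssociationResult], path, note: str | None = None
) -> None:
    imbalance, n_total = results
    payload = {
        "unit": "evaluable table (attainable or unattainable; ties excluded)",
        "outcome": "nonattainability indicator (0/1)",
        "imbalance": imbalance.to_dict("imbalance_ratio"),
        "n_total": n_total.to_dict("n_total"),
    }
    if note:
        payload["note"] = note
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
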