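"""Maturity–performance association via Spearman rank correlation.

The relationship between digital maturity and primary-health-care
performance is monotone but visibly nonlinear (it saturates at high
maturity), so the association is quantified with Spearman's rank
correlation rather than Pearson's.  Ties receive midranks.  Two confidence
intervals are offered: the Fisher z-transform closed form (default), with
standard error 1/sqrt(n − 3) on the z scale, and a seeded percentile
bootstrap over country resamples.  No causal claim is attached to either.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import is_missing
from .catalog import CountryRecord
from .index import MaturityProfile

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    method: str
    level: float
    n_dropped: int = 0

    def __post_init__(self):
        if not (-1.0 <= self.ci_low <= self.rho <= self.ci_high <= 1.0):
            raise ValueError(
                f"invalid correlation result: ci_low={self.ci_low} rho={self.rho} "
                f"ci_high={self.ci_high}"
            )


def _fisher_ci(rho: float, n: int, level: float) -> tuple[float, float]:
    if abs(rho) >= 1.0:  # arctanh diverges; the interval degenerates
        return rho, rho
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def spearman_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    method: str = "fisher",
    seed: Optional[int] = None,
    n_boot: int = 2000,
) -> CorrelationResult:
    """Spearman rho between paired per-country values, with a CI.

    Pairs with a missing member are dropped (the count is logged and
    reported).  Requires >= 4 complete pairs and non-degenerate variance in
    both variables.
    """
    pairs = [
        (float(a), float(b))
        for a, b in zip(x, y)
        if not is_missing(a) and not is_missing(b)
    ]
    n_dropped = max(len(list(x)), len(list(y))) - len(pairs)
    if n_dropped:
        logger.info("spearman_with_ci: dropped %d incomplete pairs", n_dropped)
    if len(pairs) < 4:
        raise ValueError(f"need >=4 complete pairs, got {len(pairs)}")
    xa = np.array([p[0] for p in pairs])
    ya = np.array([p[1] for p in pairs])
    if np.min(xa) == np.max(xa) or np.min(ya) == np.max(ya):
        raise ValueError("zero variance in one of the variables")
    n = len(pairs)

    rho = float(stats.spearmanr(xa, ya).statistic)
    if 1.0 - abs(rho) < 1e-12:  # snap float noise at the bounds to exact +-1
        rho = math.copysign(1.0, rho)

    if method == "fisher":
        lo, hi = _fisher_ci(rho, n, level)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            bx, by = xa[idx], ya[idx]
            if np.min(bx) == np.max(bx) or np.min(by) == np.max(by):
                boots[b] = np.nan
            else:
                boots[b] = stats.spearmanr(bx, by).statistic
        boots = boots[~np.isnan(boots)]
        alpha = 1.0 - level
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        # a percentile interval can exclude the point estimate on extreme
        # draws; widen minimally so the reported triple stays ordered
        lo, hi = float(min(lo, rho)), float(max(hi, rho))
    else:
        raise ValueError(f"unknown CI method {method!r}")

    return CorrelationResult(
        rho=rho, ci_low=lo, ci_high=hi, n=n, method=method, level=level, n_dropped=n_dropped
    )


def scatter_table(
    profiles: Sequence[MaturityProfile],
    records: Sequence[CountryRecord],
    typed: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Paired (index, performance, region[, type]) table over complete cases
    with a present performance index — the data behind the scatter plot."""
    region_of = {r.country_id: r.region for r in records}
    perf_of = {r.country_id: r.performance_index for r in records}
    type_of = {t.country_id: t.country_type for t in typed} if typed is not None else {}
    rows = []
    for p in profiles:
        if not p.complete or is_missing(perf_of.get(p.country_id)):
            continue
        row = {
            "country_id": p.country_id,
            "index": p.index,
            "performance_index": float(perf_of[p.country_id]),
            "region": region_of[p.country_id],
        }
        if type_of:
            row["country_type"] = type_of.get(p.country_id)
        rows.append(row)
    return pd.DataFrame(rows)
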