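"""Log-expenditure regressions, residual indices and efficiency quadrants.

Two ordinary-least-squares models relate the digital-maturity index and the
performance index to the natural (or base-10) logarithm of current health
expenditure per capita:

    I_i = beta0 + beta1 * log(HE_i) + e_i

The log transform reduces the heavy right skew of per-capita spending.
Residual index values (observed minus predicted) measure how a country
performs relative to what its spending level predicts; the sign pair of the
(maturity, performance) residuals places each country in one of four
spending-efficiency quadrants.  Residual normality is checked with the
Shapiro–Wilk test; a rejection is flagged but does not change the fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import is_missing
from .country_types import TypedCountry

logger = logging.getLogger(__name__)

QUADRANTS = ("high-high", "high-low", "low-high", "low-low")


@dataclass
class LogLinearFit:
    """OLS fit of an index on log expenditure, with residual diagnostics."""

    outcome: str  # "maturity" | "performance"
    beta0: float
    beta1: float
    n: int
    r_squared: float
    shapiro_w: float
    shapiro_p: float
    log_base: str  # "natural" | "10"
    country_ids: list[str] = field(default_factory=list)
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class NormalityCheck:
    w: float
    p: float
    alpha: float
    passed: bool  # True = fail-to-reject normality


@dataclass
class QuadrantAssignment:
    country_id: str
    residual_maturity: float
    residual_performance: float
    quadrant: str
    on_boundary: bool = False  # a residual was exactly zero


def _log(x: np.ndarray, log_base: str) -> np.ndarray:
    if log_base == "natural":
        return np.log(x)
    if log_base == "10":
        return np.log10(x)
    raise ValueError(f"log_base must be 'natural' or '10', got {log_base!r}")


def fit_loglinear(
    country_ids: Sequence[str],
    values: Sequence[float],
    expenditure: Sequence[float],
    outcome: str = "maturity",
    log_base: str = "natural",
) -> LogLinearFit:
    """OLS of an index on log(health expenditure), complete pairs only.

    Expenditure must be strictly positive for every included country (the
    log is undefined otherwise); the offending country is named on error.
    """
    rows = []
    for cid, v, he in zip(country_ids, values, expenditure):
        if is_missing(v) or is_missing(he):
            continue
        if float(he) <= 0:
            raise ValueError(f"country {cid!r}: expenditure must be > 0, got {he}")
        rows.append((str(cid), float(v), float(he)))
    if len(rows) < 3:
        raise ValueError(f"need >=3 complete (index, expenditure) pairs, got {len(rows)}")
    ids = [r[0] for r in rows]
    y = np.array([r[1] for r in rows])
    u = _log(np.array([r[2] for r in rows]), log_base)

    model = sm.OLS(y, sm.add_constant(u)).fit()
    resid = np.asarray(model.resid)
    if np.ptp(resid) == 0:  # perfect fit: Shapiro is undefined on constants
        w, p = float("nan"), float("nan")
    else:
        w, p = stats.shapiro(resid)
    return LogLinearFit(
        outcome=outcome,
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        n=len(rows),
        r_squared=float(model.rsquared),
        shapiro_w=float(w),
        shapiro_p=float(p),
        log_base=log_base,
        country_ids=ids,
        fitted=np.asarray(model.fittedvalues),
        residuals=resid,
    )


def predict_index(fit: LogLinearFit, expenditure: float) -> float:
    """beta0 + beta1 * log(expenditure); warns (but does not clip) outside
    the 0–100 index scale."""
    if is_missing(expenditure) or float(expenditure) <= 0:
        raise ValueError(f"expenditure must be > 0, got {expenditure}")
    pred = fit.beta0 + fit.beta1 * float(_log(np.array([float(expenditure)]), fit.log_base)[0])
    if not (0.0 <= pred <= 100.0):
        logger.warning("predicted %s index %.2f outside [0, 100]", fit.outcome, pred)
    return float(pred)


def validate_normality(residuals: Sequence[float], alpha: float = 0.05) -> NormalityCheck:
    """Shapiro–Wilk test of the residuals; pass = fail-to-reject at alpha."""
    arr = np.asarray([float(r) for r in residuals])
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk W is undefined for constant residuals")
    w, p = stats.shapiro(arr)
    return NormalityCheck(w=float(w), p=float(p), alpha=alpha, passed=bool(p >= alpha))


def assign_quadrants(
    maturity_fit: LogLinearFit,
    performance_fit: LogLinearFit,
) -> list[QuadrantAssignment]:
    """Place each country in a spending-efficiency quadrant from the signs
    of its paired residuals: (+,+) high-high, (+,−) high-low, (−,+)
    low-high, (−,−) low-low.  A zero residual counts as the high side, with
    a boundary flag.  Both fits must cover the same country set.
    """
    set_m, set_p = set(maturity_fit.country_ids), set(performance_fit.country_ids)
    if set_m != set_p:
        raise ValueError(
            "fits cover different country sets; "
            f"maturity-only={sorted(set_m - set_p)}, performance-only={sorted(set_p - set_m)}"
        )
    resid_p = dict(zip(performance_fit.country_ids, performance_fit.residuals))
    out = []
    for cid, rm in zip(maturity_fit.country_ids, maturity_fit.residuals):
        rp = float(resid_p[cid])
        rm = float(rm)
        quadrant = f"{'high' if rm >= 0 else 'low'}-{'high' if rp >= 0 else 'low'}"
        out.append(
            QuadrantAssignment(
                country_id=cid,
                residual_maturity=rm,
                residual_performance=rp,
                quadrant=quadrant,
                on_boundary=(rm == 0.0 or rp == 0.0),
            )
        )
    return out


def efficiency_report(
    assignments: Sequence[QuadrantAssignment],
    typed: Sequence[TypedCountry],
    regions: Optional[dict[str, str]] = None,
) -> dict[str, pd.DataFrame]:
    """Quadrant × country-type cross-tabulations, overall and per region.

    ``regions`` maps country_id → WHO region; when given, a table per
    region is added under the key ``region:<name>``.  Countries present in
    the assignments but not in ``typed`` (or vice versa) are an error.
    """
    type_of = {t.country_id: t.country_type for t in typed}
    missing = [a.country_id for a in assignments if a.country_id not in type_of]
    if missing:
        raise ValueError(f"no country type for: {missing}")
    df = pd.DataFrame(
        {
            "country_id": [a.country_id for a in assignments],
            "quadrant": [a.quadrant for a in assignments],
            "country_type": [type_of[a.country_id] for a in assignments],
        }
    )
    overall = (
        pd.crosstab(df["quadrant"], df["country_type"])
        .reindex(index=list(QUADRANTS), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    out = {"overall": overall}
    if regions is not None:
        df["region"] = [regions[c] for c in df["country_id"]]
        for region, sub in df.groupby("region"):
            out[f"region:{region}"] = (
                pd.crosstab(sub["quadrant"], sub["country_type"])
                .reindex(index=list(QUADRANTS), fill_value=0)
                .reindex(columns=overall.columns, fill_value=0)
                .astype(int)
            )
    return out
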