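"""Index construction: normalization, aggregation and missingness profiling.

Each indicator is first normalized to a 0–100 scale.  Two strategies are
available:

* ``minmax`` (default): linear map of the observed minimum to 0 and the
  observed maximum to 100 across the analysis set.  Requires at least two
  distinct values; a degenerate (constant) indicator is an error.
* ``fixed``: linear map of the indicator's declared natural bounds
  (e.g. [0, 100] for coverage percentages, [0, 1] for parity ratios) onto
  [0, 100], clipped.  Requires declared bounds.

The composite digital-maturity index is the unweighted mean of all 14
normalized indicators, computed only for complete cases (no index if any
indicator is missing).  Subcomponent scores are the mean of their non-missing
constituent indicators and tolerate partial data, carrying a partial flag.
Because subcomponents have different constituent counts, the index equals
the *constituent-count-weighted* mean of the subcomponent scores — not
their equal-weight mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import is_missing, percentage
from .catalog import CountryRecord, IndicatorCatalog, IndicatorDef

NormalizationStrategy = Union[str, Mapping[str, str]]


@dataclass
class MaturityProfile:
    """A country's normalized indicators, subcomponent scores and index."""

    country_id: str
    normalized: dict[str, Optional[float]]
    subcomponent_scores: dict[str, Optional[float]]
    subcomponent_partial: dict[str, bool]
    index: Optional[float]
    complete: bool


@dataclass
class MissingnessSummary:
    """Counts and percentages of countries with missing indicator data."""

    n_total: int
    n_missing_any: int
    pct_missing_any: float
    by_region: dict[str, tuple[int, int, float]]  # region -> (missing, total, pct)
    by_subcomponent: dict[str, tuple[int, int, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scope": "overall", "group": "all", "missing": self.n_missing_any,
             "total": self.n_total, "pct": self.pct_missing_any}
        ]
        for region, (m, t, p) in self.by_region.items():
            rows.append({"scope": "region", "group": region, "missing": m, "total": t, "pct": p})
        for sub, (m, t, p) in self.by_subcomponent.items():
            rows.append({"scope": "subcomponent", "group": sub, "missing": m, "total": t, "pct": p})
        return pd.DataFrame(rows)


def normalize_indicator(
    values: pd.Series,
    definition: IndicatorDef,
    strategy: str = "minmax",
) -> pd.Series:
    """Normalize one indicator's per-country raw values onto [0, 100].

    Missing values stay missing.  An indicator declared lower-is-better is
    reversed (100 − scaled) so that 100 always means most mature.
    """
    values = pd.to_numeric(values, errors="coerce")
    observed = values.dropna()
    if strategy == "minmax":
        if observed.nunique() < 2:
            raise ValueError(
                f"indicator {definition.id!r}: min-max normalization needs >=2 distinct "
                f"non-missing values (degenerate range)"
            )
        lo, hi = float(observed.min()), float(observed.max())
        scaled = 100.0 * (values - lo) / (hi - lo)
    elif strategy == "fixed":
        if definition.raw_range is None:
            raise ValueError(
                f"indicator {definition.id!r}: fixed-bounds normalization requires declared bounds"
            )
        lo, hi = definition.raw_range
        scaled = (100.0 * (values - lo) / (hi - lo)).clip(lower=0.0, upper=100.0)
    else:
        raise ValueError(f"unknown normalization strategy {strategy!r}")
    if definition.direction == "lower":
        scaled = 100.0 - scaled
    return scaled


def _strategy_for(strategy: NormalizationStrategy, indicator_id: str) -> str:
    if isinstance(strategy, str):
        return strategy
    return strategy.get(indicator_id, "minmax")


def normalize_records(
    records: Sequence[CountryRecord],
    catalog: IndicatorCatalog,
    strategy: NormalizationStrategy = "minmax",
) -> pd.DataFrame:
    """Normalize all indicators across the analysis set.

    Returns a DataFrame indexed by country_id with one column per indicator.
    Under min-max the reference distribution is the loaded analysis set.
    """
    raw = pd.DataFrame(
        {ind: [r.raw_indicators.get(ind) for r in records] for ind in catalog.indicator_ids},
        index=[r.country_id for r in records],
        dtype=float,
    )
    out = {}
    for defn in catalog.entries:
        out[defn.id] = normalize_indicator(raw[defn.id], defn, _strategy_for(strategy, defn.id))
    return pd.DataFrame(out, index=raw.index)


def compute_subcomponent_scores(
    normalized: Mapping[str, Optional[float]],
    catalog: IndicatorCatalog,
) -> tuple[dict[str, Optional[float]], dict[str, bool]]:
    """Mean of non-missing constituents per subcomponent, plus partial flags.

    A subcomponent with all constituents missing scores None; one with some
    (but not all) constituents missing gets the mean of what is available
    and ``partial=True``.
    """
    scores: dict[str, Optional[float]] = {}
    partial: dict[str, bool] = {}
    for sub in catalog.subcomponents:
        vals = [normalized.get(d.id) for d in catalog.by_subcomponent(sub)]
        present = [float(v) for v in vals if not is_missing(v)]
        scores[sub] = float(np.mean(present)) if present else None
        partial[sub] = 0 < len(present) < len(vals)
    return scores, partial


def compute_index(
    normalized: Mapping[str, Optional[float]],
    catalog: IndicatorCatalog,
) -> tuple[Optional[float], bool]:
    """Unweighted mean of all normalized indicators; complete cases only."""
    vals = [normalized.get(i) for i in catalog.indicator_ids]
    complete = all(not is_missing(v) for v in vals)
    if not complete:
        return None, False
    return float(np.mean([float(v) for v in vals])), True


def build_profiles(
    records: Sequence[CountryRecord],
    catalog: IndicatorCatalog,
    strategy: NormalizationStrategy = "minmax",
) -> list[MaturityProfile]:
    """Run normalization → subcomponent scores → index for every country."""
    normalized = normalize_records(records, catalog, strategy)
    profiles = []
    for r in records:
        norm = {
            i: (None if is_missing(normalized.at[r.country_id, i]) else float(normalized.at[r.country_id, i]))
            for i in catalog.indicator_ids
        }
        scores, partial = compute_subcomponent_scores(norm, catalog)
        index, complete = compute_index(norm, catalog)
        profiles.append(
            MaturityProfile(
                country_id=r.country_id,
                normalized=norm,
                subcomponent_scores=scores,
                subcomponent_partial=partial,
                index=index,
                complete=complete,
            )
        )
    return profiles


def summarize_missingness(
    records: Sequence[CountryRecord],
    catalog: IndicatorCatalog,
) -> MissingnessSummary:
    """Profile missing indicator data overall, by region and by subcomponent.

    A country is missing-any if at least one of the catalog's indicators is
    missing, and missing for a subcomponent if at least one of that
    subcomponent's constituents is missing.  Percentages are rounded
    half-up to one decimal.
    """
    if not records:
        raise ValueError("summarize_missingness needs at least one record")
    n_total = len(records)
    missing_any = [not r.is_complete(catalog) for r in records]
    n_missing_any = sum(missing_any)

    by_region: dict[str, tuple[int, int, float]] = {}
    regions = sorted({r.region for r in records})
    for region in regions:
        idx = [i for i, r in enumerate(records) if r.region == region]
        m = sum(missing_any[i] for i in idx)
        by_region[region] = (m, len(idx), percentage(m, len(idx)))

    by_subcomponent: dict[str, tuple[int, int, float]] = {}
    for sub in catalog.subcomponents:
        ids = [d.id for d in catalog.by_subcomponent(sub)]
        m = sum(
            1
            for r in records
            if any(is_missing(r.raw_indicators.get(i)) for i in ids)
        )
        by_subcomponent[sub] = (m, n_total, percentage(m, n_total))

    return MissingnessSummary(
        n_total=n_total,
        n_missing_any=n_missing_any,
        pct_missing_any=percentage(n_missing_any, n_total),
        by_region=by_region,
        by_subcomponent=by_subcomponent,
    )


def profiles_to_frame(profiles: Sequence[MaturityProfile], catalog: IndicatorCatalog) -> pd.DataFrame:
    """Flatten profiles to one row per country for CSV export."""
    rows = []
    for p in profiles:
        row: dict = {"country_id": p.country_id}
        for i in catalog.indicator_ids:
            row[f"norm.{i}"] = p.normalized.get(i)
        for s in catalog.subcomponents:
            row[f"sub.{s}"] = p.subcomponent_scores.get(s)
            row[f"partial.{s}"] = p.subcomponent_partial.get(s, False)
        row["index"] = p.index
        row["complete"] = p.complete
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame, catalog: IndicatorCatalog) -> list[MaturityProfile]:
    """Inverse of :func:`profiles_to_frame` (full-precision round trip)."""
    profiles = []
    for _, row in df.iterrows():
        norm = {
            i: (None if is_missing(row.get(f"norm.{i}")) else float(row[f"norm.{i}"]))
            for i in catalog.indicator_ids
        }
        scores = {
            s: (None if is_missing(row.get(f"sub.{s}")) else float(row[f"sub.{s}"]))
            for s in catalog.subcomponents
        }
        partial = {s: bool(row.get(f"partial.{s}", False)) for s in catalog.subcomponents}
        profiles.append(
            MaturityProfile(
                country_id=str(row["country_id"]),
                normalized=norm,
                subcomponent_scores=scores,
                subcomponent_partial=partial,
                index=None if is_missing(row.get("index")) else float(row["index"]),
                complete=bool(row["complete"]),
            )
        )
    return profiles
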