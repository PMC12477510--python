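"""Quartile-based country typing of the digital-maturity index.

Complete-case countries are divided into four maturity types — emerging,
transitioner, advanced, leader — at the 25th/50th/75th percentiles of their
index values.  Percentiles use linear interpolation (the common "type 7"
convention); a country whose index falls exactly on a cut point goes to the
lower type.  The published study boundaries are bundled as the named preset
``paper2023`` so new data can be classified against the original cut points
without the original dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import is_missing, round_half_up
from .catalog import CountryRecord
from .index import MaturityProfile

TYPE_LABELS = ("emerging", "transitioner", "advanced", "leader")
OUT_OF_RANGE = "out-of-range"


@dataclass(frozen=True)
class TypeBoundaries:
    """Cut points partitioning the index scale into the four type intervals.

    ``cuts`` are the upper edges of emerging/transitioner/advanced (full
    precision); ``low``/``high`` bound the covered range.  Indices outside
    [low, high] are reported as out-of-range rather than silently clamped.
    """

    low: float
    cuts: tuple[float, float, float]
    high: float

    def __post_init__(self):
        seq = (self.low, *self.cuts, self.high)
        if any(b >= a for a, b in zip(seq[1:], seq[:-1])):
            raise ValueError(f"boundaries must be strictly increasing, got {seq}")

    def intervals(self, ndigits: int = 1) -> dict[str, tuple[float, float]]:
        """Labeled intervals with bounds rounded for reporting."""
        edges = (self.low, *self.cuts, self.high)
        return {
            label: (round_half_up(edges[k], ndigits), round_half_up(edges[k + 1], ndigits))
            for k, label in enumerate(TYPE_LABELS)
        }


#: The study's printed quartile boundaries (emerging 27.9–60.3,
#: transitioner 60.4–69.8, advanced 69.9–78.3, leader 78.4–92.7).  The
#: printed intervals are adjacent at one-decimal resolution, so the upper
#: edges of the first three intervals act as the cut points.
PAPER_2023 = TypeBoundaries(low=27.9, cuts=(60.3, 69.8, 78.3), high=92.7)

PRESETS = {"paper2023": PAPER_2023}


@dataclass
class TypedCountry:
    country_id: str
    index: float
    country_type: str


def derive_boundaries(indices: Sequence[float]) -> TypeBoundaries:
    """Quartile cut points of the supplied index values.

    Uses linear-interpolation percentiles over at least 4 distinct-ranged
    values; an all-equal input has no quartiles and is an error.
    """
    arr = np.asarray([v for v in indices if not is_missing(v)], dtype=float)
    if arr.size < 4:
        raise ValueError(f"need >=4 index values to derive quartiles, got {arr.size}")
    if np.min(arr) == np.max(arr):
        raise ValueError("degenerate quartiles: all index values are equal")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return TypeBoundaries(low=float(np.min(arr)), cuts=(float(q1), float(q2), float(q3)),
                          high=float(np.max(arr)))


def classify_country(index: float, boundaries: TypeBoundaries) -> str:
    """Label of the interval containing ``index``; ties at a cut point go to
    the lower type; outside [low, high] → explicit out-of-range."""
    if is_missing(index):
        raise ValueError("cannot classify a missing index")
    x = float(index)
    if x < boundaries.low or x > boundaries.high:
        return OUT_OF_RANGE
    for cut, label in zip(boundaries.cuts, TYPE_LABELS[:3]):
        if x <= cut:
            return label
    return TYPE_LABELS[3]


def classify_profiles(
    profiles: Sequence[MaturityProfile],
    boundaries: Optional[TypeBoundaries] = None,
) -> tuple[list[TypedCountry], TypeBoundaries]:
    """Type every complete-case profile; derive boundaries from the same
    profiles when none are given."""
    complete = [p for p in profiles if p.complete]
    if boundaries is None:
        boundaries = derive_boundaries([p.index for p in complete])
    typed = [
        TypedCountry(p.country_id, float(p.index), classify_country(p.index, boundaries))
        for p in complete
    ]
    return typed, boundaries


def summarize_types_by_region(
    typed: Sequence[TypedCountry],
    records: Sequence[CountryRecord],
) -> tuple[pd.DataFrame, pd.Series]:
    """Region × type contingency table and per-region mean index (1 d.p.)."""
    if not typed:
        raise ValueError("no typed countries to summarize")
    region_of = {r.country_id: r.region for r in records}
    df = pd.DataFrame(
        {
            "region": [region_of[t.country_id] for t in typed],
            "country_type": [t.country_type for t in typed],
            "index": [t.index for t in typed],
        }
    )
    labels = [l for l in (*TYPE_LABELS, OUT_OF_RANGE) if l in set(df["country_type"])]
    table = pd.crosstab(df["region"], df["country_type"]).reindex(columns=labels, fill_value=0)
    means = df.groupby("region")["index"].mean().map(lambda v: round_half_up(v, 1))
    return table, means
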