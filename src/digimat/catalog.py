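"""Indicator catalog and country-level data model.

The digital-maturity-in-health index aggregates 14 country-level indicators
(3G coverage, e-government services, electricity access, ICT skills,
GovTech maturity, technology investment and regulation, privacy law,
cybersecurity, gender gaps in digital access, phone ownership) into 7
thematic subcomponents and one 0–100 composite.  The catalog describing
which indicator belongs to which subcomponent is configuration, not code:
the bundled default mirrors the published 14-indicator set, but any catalog
can be supplied through a YAML file.  ``strict`` validation enforces the
published shape (14 indicators, 7 subcomponents with constituent counts
3/1/1/2/4/2/1); non-strict validation accepts arbitrary catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from ._util import is_missing

#: The six WHO administrative regions used for stratified reporting.
WHO_REGIONS = (
    "African",
    "Americas",
    "South-East Asia",
    "European",
    "Eastern Mediterranean",
    "Western Pacific",
)

#: Constituent-indicator counts per subcomponent required in strict mode.
STRICT_SUBCOMPONENT_COUNTS = {
    "infrastructure": 3,
    "workforce": 1,
    "leadership-and-governance": 1,
    "strategy-and-investment": 2,
    "legislation-policy-and-compliance": 4,
    "gender-diversity": 2,
    "consumer-readiness": 1,
}

#: Reserved column names in country tables (everything else must be an
#: indicator id known to the catalog).
RESERVED_COLUMNS = ("country_id", "region", "health_expenditure", "performance_index")


@dataclass(frozen=True)
class IndicatorDef:
    """One indicator: identity, subcomponent membership, orientation, bounds.

    ``direction`` is "higher" when larger raw values mean more maturity.
    All 14 default indicators are higher-is-better, including the two
    gender-gap ratios, which are parity ratios where 1 (parity) is the
    maximum good.  ``raw_range`` declares natural bounds for the
    fixed-bounds normalization strategy; None means unbounded.
    """

    id: str
    subcomponent: str
    direction: str = "higher"
    raw_range: Optional[tuple[float, float]] = None
    label: str = ""

    def __post_init__(self):
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"direction must be 'higher' or 'lower', got {self.direction!r}")
        if self.raw_range is not None:
            lo, hi = self.raw_range
            if not lo < hi:
                raise ValueError(f"indicator {self.id!r}: raw_range must satisfy low < high")


@dataclass
class IndicatorCatalog:
    """An ordered set of indicators grouped into subcomponents."""

    entries: list[IndicatorDef]
    subcomponents: list[str]
    region_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate(strict=False)

    # -- validation ---------------------------------------------------------

    def validate(self, strict: bool = False) -> None:
        """Check internal consistency; ``strict`` additionally enforces the
        published 14-indicator / 7-subcomponent shape."""
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")
        if len(self.subcomponents) != len(set(self.subcomponents)):
            raise ValueError("duplicate subcomponent names")
        for e in self.entries:
            if e.subcomponent not in self.subcomponents:
                raise ValueError(
                    f"indicator {e.id!r} references unknown subcomponent {e.subcomponent!r}"
                )
        if strict:
            if len(self.entries) != 14:
                raise ValueError(f"strict catalog requires 14 indicators, got {len(self.entries)}")
            if len(self.subcomponents) != 7:
                raise ValueError(
                    f"strict catalog requires 7 subcomponents, got {len(self.subcomponents)}"
                )
            counts = self.constituent_counts()
            if counts != STRICT_SUBCOMPONENT_COUNTS:
                raise ValueError(
                    f"strict catalog constituent counts {counts} != {STRICT_SUBCOMPONENT_COUNTS}"
                )

    # -- access -------------------------------------------------------------

    @property
    def indicator_ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def get(self, indicator_id: str) -> IndicatorDef:
        for e in self.entries:
            if e.id == indicator_id:
                return e
        raise KeyError(indicator_id)

    def by_subcomponent(self, name: str) -> list[IndicatorDef]:
        if name not in self.subcomponents:
            raise KeyError(name)
        return [e for e in self.entries if e.subcomponent == name]

    def constituent_counts(self) -> dict[str, int]:
        return {s: len(self.by_subcomponent(s)) for s in self.subcomponents}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "IndicatorCatalog":
        entries = []
        for row in config["indicators"]:
            raw_range = row.get("raw_range")
            entries.append(
                IndicatorDef(
                    id=row["id"],
                    subcomponent=row["subcomponent"],
                    direction=row.get("direction", "higher"),
                    raw_range=tuple(raw_range) if raw_range is not None else None,
                    label=row.get("label", ""),
                )
            )
        return cls(
            entries=entries,
            subcomponents=list(config["subcomponents"]),
            region_aliases=dict(config.get("region_aliases", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "IndicatorCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_config(yaml.safe_load(fh))


def default_catalog() -> IndicatorCatalog:
    """The bundled 14-indicator / 7-subcomponent catalog."""
    text = resources.files("digimat").joinpath("data/default_catalog.yml").read_text("utf-8")
    cat = IndicatorCatalog.from_config(yaml.safe_load(text))
    cat.validate(strict=True)
    return cat


def resolve_region(value: str, aliases: Optional[Mapping[str, str]] = None) -> str:
    """Map a region name or alias (e.g. ``EURO``) onto the canonical WHO
    region name; raise on anything unrecognized."""
    value = str(value).strip()
    if value in WHO_REGIONS:
        return value
    if aliases and value in aliases:
        canonical = aliases[value]
        if canonical not in WHO_REGIONS:
            raise ValueError(f"alias {value!r} maps to unknown region {canonical!r}")
        return canonical
    raise ValueError(f"unknown WHO region {value!r}; expected one of {WHO_REGIONS} or an alias")


@dataclass
class CountryRecord:
    """One country's raw inputs to the analysis.

    ``raw_indicators`` maps indicator id to a raw value or None (missing).
    ``health_expenditure`` is current health expenditure per capita in US$
    (must be > 0 when present); ``performance_index`` is the primary-health-
    care performance index on a 0–100 scale, treated as a given input.
    """

    country_id: str
    region: str
    raw_indicators: dict[str, Optional[float]]
    health_expenditure: Optional[float] = None
    performance_index: Optional[float] = None

    def __post_init__(self):
        if self.region not in WHO_REGIONS:
            raise ValueError(f"{self.country_id}: unknown region {self.region!r}")
        if not is_missing(self.performance_index) and not (
            0.0 <= float(self.performance_index) <= 100.0
        ):
            raise ValueError(
                f"{self.country_id}: performance_index {self.performance_index} outside [0, 100]"
            )
        if not is_missing(self.health_expenditure) and float(self.health_expenditure) <= 0:
            raise ValueError(
                f"{self.country_id}: health_expenditure must be > 0, got {self.health_expenditure}"
            )

    def missing_indicators(self, catalog: IndicatorCatalog) -> list[str]:
        return [i for i in catalog.indicator_ids if is_missing(self.raw_indicators.get(i))]

    def is_complete(self, catalog: IndicatorCatalog) -> bool:
        return not self.missing_indicators(catalog)
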