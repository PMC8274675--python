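"""Pipeline configuration and the POI category -> group mapping.

The category map is a total function from raw POI categories to a
``(group, tag)`` pair, where ``group`` is one of ``food``, ``sports``,
``other`` and ``tag`` is the place family used by the indicator and
environment tables (fast food/takeaway, supermarket/grocery, restaurant,
athletics/sports facility, indoor recreation, public park). Food-related
place families feed the "food" composite, sports-related ones the "sports"
composite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import yaml

from .errors import ConfigError

GROUPS = ("food", "sports", "other")

FOOD_TAGS = ("fast_food_takeaway", "supermarket_grocery", "restaurant")
SPORTS_TAGS = ("sports_facility", "indoor_recreation", "park")
ALL_TAGS = FOOD_TAGS + SPORTS_TAGS

#: Raw POI category -> (group, tag). Mirrors the common open-data vocabularies.
DEFAULT_CATEGORY_MAP: dict[str, tuple[str, str]] = {
    "fast_food": ("food", "fast_food_takeaway"),
    "takeaway": ("food", "fast_food_takeaway"),
    "supermarket": ("food", "supermarket_grocery"),
    "grocery": ("food", "supermarket_grocery"),
    "convenience": ("food", "supermarket_grocery"),
    "restaurant": ("food", "restaurant"),
    "cafe": ("food", "restaurant"),
    "sports_facility": ("sports", "sports_facility"),
    "stadium": ("sports", "sports_facility"),
    "pitch": ("sports", "sports_facility"),
    "gym": ("sports", "indoor_recreation"),
    "swimming_pool": ("sports", "indoor_recreation"),
    "indoor_recreation": ("sports", "indoor_recreation"),
    "park": ("sports", "park"),
    "playground": ("sports", "park"),
}


class CategoryGroupMap:
    """Total mapping from POI categories to (group, tag)."""

    def __init__(self, mapping: Mapping[str, tuple[str, str]] | None = None):
        self._map = dict(DEFAULT_CATEGORY_MAP if mapping is None else mapping)
        for cat, (group, tag) in self._map.items():
            if group not in GROUPS:
                raise ConfigError(f"category {cat!r}: unknown group {group!r}")
            if group != "other" and tag not in ALL_TAGS:
                raise ConfigError(f"category {cat!r}: unknown tag {tag!r}")

    @classmethod
    def from_yaml(cls, path) -> "CategoryGroupMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({cat: (spec["group"], spec.get("tag", "other")) for cat, spec in raw.items()})

    def group(self, category: str) -> str:
        return self._lookup(category)[0]

    def tag(self, category: str) -> str:
        return self._lookup(category)[1]

    def _lookup(self, category: str) -> tuple[str, str]:
        try:
            return self._map[category]
        except KeyError:
            raise ConfigError(f"POI category {category!r} missing from the category-group map") from None

    def tags_in_group(self, group: str) -> tuple[str, ...]:
        if group == "food":
            return FOOD_TAGS
        if group == "sports":
            return SPORTS_TAGS
        raise ConfigError(f"no composite defined for group {group!r}")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self._map)


@dataclass(frozen=True)
class PeriodSpec:
    """An inclusive calendar-date window used by the before/after comparison."""

    label: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"period {self.label!r}: start {self.start} after end {self.end}")

    def overlaps(self, other: "PeriodSpec") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the explore/explain/compare pipeline.

    Defaults encode the dashboard's published rules: 1-minute minimum visit,
    10-minute minimum for sports-related visit percentages, >60 recorded
    minutes for a day to count toward resident daily steps, suppression of
    aggregates with 5 or fewer contributors, 7-digit geohashes, a strict
    1000-m school radius, and the 30-m grid / 100-m radius density.
    """

    precision: int = 7
    min_visit_min: float = 1.0
    min_sport_visit_min: float = 10.0
    day_min: float = 60.0
    suppress_n: int = 5
    school_radius_m: float = 1000.0
    grid_spacing_m: float = 30.0
    poi_radius_m: float = 100.0
    max_gap_min: float = 5.0
    poi_contact_radius_m: float = 50.0
    poi_dwell_min: float = 1.0
    night_window: tuple[int, int] = (0, 6)  # hours of day, [start, end)
    category_map: CategoryGroupMap = field(default_factory=CategoryGroupMap)

    def __post_init__(self) -> None:
        for name in ("min_visit_min", "min_sport_visit_min", "day_min", "school_radius_m",
                     "grid_spacing_m", "poi_radius_m", "max_gap_min", "poi_contact_radius_m",
                     "poi_dwell_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.precision not in range(1, 13):
            raise ConfigError(f"precision must be in 1..12, got {self.precision}")
        if self.suppress_n < 0:
            raise ConfigError("suppress_n must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load thresholds (and optionally a category map) from a YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path!r} must contain a mapping")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        if "category_map" in kwargs:
            kwargs["category_map"] = CategoryGroupMap(
                {cat: (spec["group"], spec.get("tag", "other")) for cat, spec in kwargs["category_map"].items()})
        if "night_window" in kwargs:
            kwargs["night_window"] = tuple(kwargs["night_window"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["category_map"] = {c: list(self.category_map._lookup(c)) for c in self.category_map.categories}
        d["night_window"] = list(self.night_window)
        return d
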