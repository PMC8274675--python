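"""Behavioral indicators aggregated per geohash cell.

Three aggregation bases exist:

``visits``
    the unweighted mean over all stays in the cell, repeat stays by the same
    child counted separately;
``visitors``
    each child's stays in the cell are pooled first (total steps / total
    time), then the mean is taken over unique children;
``residents``
    the child's behavior *everywhere* is summarised (daily steps over days
    with more than 60 recorded minutes) and attributed to the child's home
    cell — a guard against the residential fallacy.

All functions return a long-format table with columns
``region_id, indicator, basis, value, n_contributors``; cells with no
eligible contribution are simply absent. :func:`suppress_low_support`
applies the privacy rule: an aggregate is published only when *more than*
``min_n`` contributions (on the value's own basis) back it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import FOOD_TAGS, SPORTS_TAGS, PipelineConfig
from .errors import ConfigError

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["region_id", "indicator", "basis", "value", "n_contributors"]


def _table(region_id, indicator: str, basis: str, value, n) -> pd.DataFrame:
    return pd.DataFrame({
        "region_id": region_id,
        "indicator": indicator,
        "basis": basis,
        "value": np.asarray(value, dtype=float),
        "n_contributors": np.asarray(n, dtype=np.int64),
    })[TABLE_COLUMNS]


def _empty() -> pd.DataFrame:
    return _table([], "", "", [], [])


def steps_per_hour_by_visits(visits: pd.DataFrame, min_duration_min: float = 1.0) -> pd.DataFrame:
    """Mean steps/hour over visits to each cell (repeats counted)."""
    v = visits[visits["duration_min"] >= min_duration_min]
    if len(v) == 0:
        return _empty()
    rate = v["steps"].to_numpy() / (v["duration_min"].to_numpy() / 60.0)
    g = pd.DataFrame({"code": v["code"].to_numpy(), "rate": rate}).groupby("code")["rate"].agg(["mean", "size"])
    return _table(g.index.to_numpy(), "steps_per_hour", "visits", g["mean"].to_numpy(), g["size"].to_numpy())


def steps_per_hour_by_visitors(visits: pd.DataFrame, min_duration_min: float = 1.0) -> pd.DataFrame:
    """Mean steps/hour over unique visitors of each cell (stays pooled per child)."""
    v = visits[visits["duration_min"] >= min_duration_min]
    if len(v) == 0:
        return _empty()
    per_child = v.groupby(["code", "child_id"], as_index=False).agg(
        steps=("steps", "sum"), minutes=("duration_min", "sum"))
    per_child["rate"] = per_child["steps"] / (per_child["minutes"] / 60.0)
    g = per_child.groupby("code")["rate"].agg(["mean", "size"])
    return _table(g.index.to_numpy(), "steps_per_hour", "visitors", g["mean"].to_numpy(), g["size"].to_numpy())


def pct_visits_with_place(
    visits: pd.DataFrame,
    place: str,
    min_duration_min: float,
    indicator: str | None = None,
) -> pd.DataFrame:
    """Percentage of eligible visits that contact at least one place of a family.

    ``place`` is either a tag (``fast_food_takeaway``, ``supermarket_grocery``,
    ``restaurant``, ``sports_facility``, ``indoor_recreation``, ``park``) or a
    group (``food``, ``sports``), matched against the ``contacts_<tag>``
    columns produced by :func:`geobehave.trajectory.attach_poi_contacts`.
    Eligibility is the duration filter: 1 minute for food-type indicators,
    10 minutes for sports-type ones.
    """
    if place == "food":
        tags = FOOD_TAGS
    elif place == "sports":
        tags = SPORTS_TAGS
    elif place in FOOD_TAGS + SPORTS_TAGS:
        tags = (place,)
    else:
        raise ConfigError(f"unknown place family {place!r}")
    cols = [f"contacts_{t}" for t in tags]
    missing = [c for c in cols if c not in visits.columns]
    if missing:
        raise ConfigError(f"visits table lacks contact columns {missing}; run attach_poi_contacts first")

    v = visits[visits["duration_min"] >= min_duration_min]
    if len(v) == 0:
        return _empty()
    hit = (v[cols].to_numpy().sum(axis=1) > 0).astype(float)
    g = pd.DataFrame({"code": v["code"].to_numpy(), "hit": hit}).groupby("code")["hit"].agg(["mean", "size"])
    name = indicator or f"pct_visits_{place}"
    return _table(g.index.to_numpy(), name, "visits", 100.0 * g["mean"].to_numpy(), g["size"].to_numpy())


def daily_steps_residents(
    residences: pd.DataFrame,
    day_summaries: pd.DataFrame,
    day_min: float = 60.0,
) -> pd.DataFrame:
    """Mean daily steps of each cell's residents, over days with > ``day_min`` recorded minutes.

    The day summaries cover the child's fixes anywhere on the map, so the
    value attributed to the home cell reflects behavior that may have
    happened elsewhere. Residents without a qualifying day are excluded from
    both the mean and the contributor count.
    """
    if len(residences) == 0 or len(day_summaries) == 0:
        return _empty()
    q = day_summaries[day_summaries["recorded_min"] > day_min]
    if len(q) == 0:
        return _empty()
    per_child = q.groupby("child_id", as_index=False)["steps"].mean()
    joined = per_child.merge(residences[["child_id", "code"]], on="child_id", how="inner")
    if len(joined) == 0:
        return _empty()
    g = joined.groupby("code")["steps"].agg(["mean", "size"])
    return _table(g.index.to_numpy(), "daily_steps", "residents", g["mean"].to_numpy(), g["size"].to_numpy())


def suppress_low_support(table: pd.DataFrame, min_n: int = 5) -> pd.DataFrame:
    """Retain only aggregates backed by strictly more than ``min_n`` contributions."""
    keep = table["n_contributors"] > min_n
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("suppressed %d aggregate(s) with <= %d contributors", n_drop, min_n)
    return table[keep].reset_index(drop=True)


def compute_indicator_table(
    visits: pd.DataFrame,
    residences: pd.DataFrame | None = None,
    day_summaries: pd.DataFrame | None = None,
    cfg: PipelineConfig | None = None,
    suppress: bool = True,
) -> pd.DataFrame:
    """All indicators for one visits table, optionally suppression-filtered.

    Emits steps/hour on both the visits and visitors bases, the percentage of
    visits contacting each place family (food families at the 1-minute filter,
    sports families at the 10-minute filter) plus the any-food-place variant,
    and — when residences and day summaries are given — resident daily steps.
    """
    cfg = cfg or PipelineConfig()
    parts = [
        steps_per_hour_by_visits(visits, cfg.min_visit_min),
        steps_per_hour_by_visitors(visits, cfg.min_visit_min),
    ]
    has_contacts = any(c.startswith("contacts_") for c in visits.columns)
    if has_contacts:
        parts.append(pct_visits_with_place(visits, "food", cfg.min_visit_min))
        for tag in FOOD_TAGS:
            parts.append(pct_visits_with_place(visits, tag, cfg.min_visit_min))
        for tag in SPORTS_TAGS:
            parts.append(pct_visits_with_place(visits, tag, cfg.min_sport_visit_min))
    if residences is not None and day_summaries is not None:
        parts.append(daily_steps_residents(residences, day_summaries, cfg.day_min))
    table = pd.concat(parts, ignore_index=True)
    if suppress:
        table = suppress_low_support(table, cfg.suppress_n)
    return table
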