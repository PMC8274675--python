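"""Explore / explain / compare orchestration over file or in-memory inputs.

These functions tie the stages together exactly as the CLI exposes them:

- :func:`explore` — trajectories + POI layer -> suppressed behavioral
  indicator table and environment table;
- :func:`explain` — explore outputs + schools -> per-city behavior x
  environment correlation report over school-proximal cells;
- :func:`compare` — trajectories + municipality boundaries + two periods ->
  municipality-level before/after comparison.

Every run produces a manifest (config snapshot, input digests, per-stage
record counts) so that any published table can be traced to its inputs and
thresholds. Tables are written as CSV and as JSON record arrays (the
dashboard-style export).
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone

import pandas as pd

from . import __version__, association, environment, indicators, temporal, trajectory
from .config import PeriodSpec, PipelineConfig


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(cfg: PipelineConfig, inputs: dict, counts: dict) -> dict:
    return {
        "tool": "geobehave",
        "version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": cfg.snapshot(),
        "inputs": {k: _digest(v) for k, v in inputs.items() if v is not None and os.path.exists(str(v))},
        "counts": counts,
    }


def prepare_visits(fixes: pd.DataFrame, pois: pd.DataFrame | None, cfg: PipelineConfig):
    """Segment fixes and attach POI contacts; returns (visits, stats)."""
    visits, fvid, stats = trajectory.segment_visits(
        fixes, cfg.precision, cfg.min_visit_min, cfg.max_gap_min)
    if pois is not None and len(pois):
        f = trajectory._sorted_fixes(fixes)
        visits = trajectory.attach_poi_contacts(
            f, fvid, visits, pois, cfg.category_map, cfg.poi_contact_radius_m, cfg.poi_dwell_min)
    return visits, stats


def explore(fixes: pd.DataFrame, pois: pd.DataFrame | None, cfg: PipelineConfig | None = None,
            input_paths: dict | None = None):
    """Indicator + environment tables for one trajectory/POI input.

    Returns ``(indicator_table, env_table, manifest)``; the indicator table
    is already suppression-filtered and the manifest's ``cells_suppressed``
    records how many aggregates the more-than-``suppress_n`` rule removed.
    """
    cfg = cfg or PipelineConfig()
    visits, stats = prepare_visits(fixes, pois, cfg)
    days = trajectory.summarize_days(fixes, cfg.max_gap_min)
    residences = trajectory.assign_residence(fixes, cfg.precision, cfg.night_window, cfg.max_gap_min)

    unsuppressed = indicators.compute_indicator_table(visits, residences, days, cfg, suppress=False)
    table = indicators.suppress_low_support(unsuppressed, cfg.suppress_n)

    cells = table["region_id"].unique()
    if pois is not None and len(pois) and len(cells):
        env = environment.environment_table(pois, cells, cfg.category_map, cfg.grid_spacing_m, cfg.poi_radius_m)
    else:
        env = pd.DataFrame(columns=environment.ENV_COLUMNS)

    counts = {
        "fixes": int(len(fixes)),
        "children": int(fixes["child_id"].nunique()) if len(fixes) else 0,
        "visit_candidates": stats["candidates"],
        "visits_retained": stats["retained"],
        "visits_dropped_short": stats["dropped_short"],
        "gap_splits": stats["gap_splits"],
        "indicator_rows": int(len(unsuppressed)),
        "cells_suppressed": int(len(unsuppressed) - len(table)),
        "residents": int(len(residences)),
    }
    return table, env, _manifest(cfg, input_paths or {}, counts)


def explain(indicator_table: pd.DataFrame, env_table: pd.DataFrame, schools: pd.DataFrame,
            cfg: PipelineConfig | None = None, pairings=association.DEFAULT_PAIRINGS,
            bh_correct: bool = False) -> pd.DataFrame:
    """Per-city association report over school-proximal geohashes."""
    cfg = cfg or PipelineConfig()
    return association.associate(indicator_table, env_table, schools, pairings,
                                 cfg.school_radius_m, cfg.precision, bh_correct)


def compare(fixes: pd.DataFrame, municipalities, before: PeriodSpec, after: PeriodSpec,
            cfg: PipelineConfig | None = None, basis: str = "visitors",
            min_support: int = 1) -> pd.DataFrame:
    """Municipality-level before/after comparison of steps/hour."""
    cfg = cfg or PipelineConfig()
    visits, _, _ = trajectory.segment_visits(fixes, cfg.precision, cfg.min_visit_min, cfg.max_gap_min)
    return temporal.compare_periods(visits, municipalities, before, after, basis,
                                    cfg.precision, cfg.min_visit_min, min_support)


def write_tables(outdir, **tables) -> None:
    """Write each table as ``<name>.csv`` and ``<name>.json`` (record array)."""
    os.makedirs(outdir, exist_ok=True)
    for name, table in tables.items():
        if table is None:
            continue
        if isinstance(table, dict):
            with open(os.path.join(outdir, f"{name}.json"), "w") as fh:
                json.dump(table, fh, indent=2, default=str)
            continue
        table.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        with open(os.path.join(outdir, f"{name}.json"), "w") as fh:
            json.dump(json.loads(table.to_json(orient="records", date_format="iso")), fh, indent=2)
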