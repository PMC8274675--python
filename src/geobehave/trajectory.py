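"""Fix ingestion and segmentation into geohash visits.

A *fix* is one timestamped GPS sample for one child carrying the step count
accrued since that child's previous fix. Fix streams are segmented into
*visits*: maximal runs of consecutive fixes that encode to the same geohash
cell, split wherever the time gap between consecutive fixes exceeds
``max_gap_min`` (sparse sampling must not fabricate long stays), and dropped
when shorter than ``min_duration_min``.

Bulk data moves through the package as pandas DataFrames; the dataclasses
below document the per-record schema. Step increments are attributed to the
interval *ending* at their fix, so the entry fix of a visit contributes no
steps to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geocode
from .config import CategoryGroupMap
from .errors import InputError

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["child_id", "timestamp", "lat", "lon", "steps"]


@dataclass(frozen=True)
class Fix:
    child_id: str
    t: datetime
    lat: float
    lon: float
    steps: int


@dataclass(frozen=True)
class Visit:
    child_id: str
    cell: str
    t_entry: datetime
    t_exit: datetime
    duration_min: float
    steps: int
    poi_contacts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DaySummary:
    child_id: str
    date: object
    recorded_min: float
    steps: int


@dataclass(frozen=True)
class Residence:
    child_id: str
    cell: str


def load_fixes(path_or_buffer, strict: bool = False) -> pd.DataFrame:
    """Read a trajectory CSV into a validated, (child, time)-sorted DataFrame.

    Expected header: ``child_id,timestamp,lat,lon,steps`` with ISO-8601
    timestamps. Invalid rows (unparsable timestamp, out-of-range coordinates,
    negative steps, duplicated timestamp within a child) raise
    :class:`InputError` naming the offending line when ``strict`` is true and
    are skipped with a logged warning otherwise.
    """
    raw = pd.read_csv(path_or_buffer, dtype={"child_id": str})
    missing = [c for c in FIX_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"trajectory CSV missing columns: {missing}")
    # +2: 1-based lines, one header line
    lines = raw.index.to_numpy() + 2

    t = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True, format="ISO8601")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    steps = pd.to_numeric(raw["steps"], errors="coerce")

    bad = pd.Series("", index=raw.index, dtype=object)
    bad[t.isna()] = "unparsable timestamp"
    bad[lat.isna() | (lat < -90) | (lat > 90)] = "latitude out of range"
    bad[lon.isna() | (lon < -180) | (lon >= 180)] = "longitude out of range"
    bad[steps.isna() | (steps < 0)] = "negative or missing steps"
    dup = pd.DataFrame({"c": raw["child_id"], "t": t}).duplicated(keep="first") & t.notna()
    bad[dup] = "duplicate timestamp for child"

    bad_mask = bad != ""
    if bad_mask.any():
        first = int(np.flatnonzero(bad_mask)[0])
        msg = f"line {lines[first]}: {bad.iloc[first]}"
        if strict:
            raise InputError(msg)
        for i in np.flatnonzero(bad_mask)[:20]:
            logger.warning("skipping line %d: %s", lines[i], bad.iloc[int(i)])
        if bad_mask.sum() > 20:
            logger.warning("... %d invalid rows skipped in total", int(bad_mask.sum()))

    out = pd.DataFrame({
        "child_id": raw["child_id"],
        "t": t,
        "lat": lat.astype(float),
        "lon": lon.astype(float),
        "steps": steps,
    })[~bad_mask.to_numpy()]
    out["steps"] = out["steps"].astype(np.int64)
    out = out.sort_values(["child_id", "t"], kind="mergesort").reset_index(drop=True)
    return out


def _t_ns(f: pd.DataFrame) -> np.ndarray:
    """Timestamps as int64 epoch nanoseconds (object-dtype-free arithmetic)."""
    return pd.DatetimeIndex(f["t"]).asi8


def _sorted_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    f = fixes
    if len(f) < 2:
        return f.reset_index(drop=True)
    child = f["child_id"].to_numpy()
    t = _t_ns(f)
    ordered = (child[1:] > child[:-1]) | ((child[1:] == child[:-1]) & (t[1:] > t[:-1]))
    if not ordered.all():
        f = f.sort_values(["child_id", "t"], kind="mergesort").reset_index(drop=True)
    return f


def segment_visits(
    fixes: pd.DataFrame,
    precision: int,
    min_duration_min: float = 1.0,
    max_gap_min: float = 5.0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Segment (possibly multi-child) fixes into geohash visits.

    Returns ``(visits, fix_visit_id, stats)`` where ``visits`` has one row per
    retained visit (``visit_id, child_id, cell, code, t_entry, t_exit,
    duration_min, steps``), ``fix_visit_id`` maps each row of the time-sorted
    ``fixes`` to its visit id (-1 when the fix belongs to no retained visit),
    and ``stats`` reconciles the run bookkeeping
    (``candidates == retained + dropped_short``).
    """
    f = _sorted_fixes(fixes)
    n = len(f)
    empty_visits = pd.DataFrame(columns=["visit_id", "child_id", "cell", "code", "t_entry", "t_exit", "duration_min", "steps"])
    if n == 0:
        return empty_visits, np.empty(0, dtype=np.int64), {"candidates": 0, "retained": 0, "dropped_short": 0, "gap_splits": 0}

    cell = geocode.encode_int_arrays(f["lat"].to_numpy(), f["lon"].to_numpy(), precision)
    child = f["child_id"].to_numpy()
    t = _t_ns(f)
    dt_min = np.empty(n)
    dt_min[0] = np.inf
    dt_min[1:] = np.diff(t) / 60e9

    same_child = np.zeros(n, dtype=bool)
    same_child[1:] = child[1:] == child[:-1]
    same_cell = np.zeros(n, dtype=bool)
    same_cell[1:] = cell[1:] == cell[:-1]
    gap = dt_min > max_gap_min
    new_run = ~(same_child & same_cell & ~gap)
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1

    starts = np.flatnonzero(new_run)
    ends = np.r_[starts[1:] - 1, n - 1]
    steps = f["steps"].to_numpy()
    run_steps = np.add.reduceat(steps, starts) - steps[starts]  # entry fix excluded
    t_entry = t[starts]
    t_exit = t[ends]
    duration_min = (t_exit - t_entry) / 60e9

    keep = duration_min >= min_duration_min
    stats = {
        "candidates": int(n_runs),
        "retained": int(keep.sum()),
        "dropped_short": int((~keep).sum()),
        "gap_splits": int((same_child & same_cell & gap).sum()),
    }

    visit_of_run = np.full(n_runs, -1, dtype=np.int64)
    visit_of_run[keep] = np.arange(keep.sum())
    fix_visit_id = visit_of_run[run_id]

    cells_kept = cell[starts[keep]]
    visits = pd.DataFrame({
        "visit_id": np.arange(keep.sum()),
        "child_id": child[starts[keep]],
        "cell": cells_kept,
        "code": geocode.int_to_code(cells_kept, precision),
        "t_entry": pd.to_datetime(t_entry[keep], utc=True),
        "t_exit": pd.to_datetime(t_exit[keep], utc=True),
        "duration_min": duration_min[keep],
        "steps": run_steps[keep],
    })
    return visits, fix_visit_id, stats


def _local_xy(lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float) -> np.ndarray:
    """Equirectangular metres relative to (lat0, lon0); fine at city scale."""
    m_per_deg = 2 * np.pi * geocode.EARTH_RADIUS_M / 360.0
    x = (np.asarray(lon) - lon0) * m_per_deg * np.cos(np.radians(lat0))
    y = (np.asarray(lat) - lat0) * m_per_deg
    return np.column_stack([x, y])


def attach_poi_contacts(
    fixes: pd.DataFrame,
    fix_visit_id: np.ndarray,
    visits: pd.DataFrame,
    pois: pd.DataFrame,
    category_map: CategoryGroupMap,
    contact_radius_m: float = 50.0,
    min_dwell_min: float = 1.0,
) -> pd.DataFrame:
    """Count POI contacts per visit and tag (``contacts_<tag>`` columns).

    A visit *contacts* a POI when the accumulated time over intervals whose
    both endpoint fixes lie within ``contact_radius_m`` of the POI reaches
    ``min_dwell_min``. ``fixes`` must be the time-sorted frame that produced
    ``fix_visit_id`` (as returned by :func:`segment_visits`).
    """
    from .config import ALL_TAGS

    out = visits.copy()
    for tag in ALL_TAGS:
        out[f"contacts_{tag}"] = 0
    if len(visits) == 0 or len(pois) == 0 or len(fixes) == 0:
        return out

    f = _sorted_fixes(fixes)
    in_visit = fix_visit_id >= 0
    tags = pois["category"].map(category_map.tag).to_numpy()

    lat0 = float(f["lat"].mean())
    lon0 = float(f["lon"].mean())
    fxy = _local_xy(f["lat"].to_numpy()[in_visit], f["lon"].to_numpy()[in_visit], lat0, lon0)
    pxy = _local_xy(pois["lat"].to_numpy(), pois["lon"].to_numpy(), lat0, lon0)
    tree = cKDTree(pxy)
    neighbors = tree.query_ball_point(fxy, contact_radius_m)

    fix_idx_all = np.flatnonzero(in_visit)
    pair_fix, pair_poi = [], []
    for i, lst in zip(fix_idx_all, neighbors):
        if lst:
            pair_fix.extend([i] * len(lst))
            pair_poi.extend(lst)
    if not pair_fix:
        return out
    pairs = pd.DataFrame({"fix": np.asarray(pair_fix), "poi": np.asarray(pair_poi)})

    t = _t_ns(f)
    vid = np.asarray(fix_visit_id)
    # An interval is indexed by its ending fix i and exists when fix i-1
    # belongs to the same visit.
    prev_same = np.zeros(len(f), dtype=bool)
    prev_same[1:] = (vid[1:] >= 0) & (vid[1:] == vid[:-1])
    dt_min = np.zeros(len(f))
    dt_min[1:] = np.diff(t) / 60e9

    end = pairs[prev_same[pairs["fix"]]]
    start = pairs.assign(fix=pairs["fix"] + 1)
    both = end.merge(start, on=["fix", "poi"], how="inner")
    if len(both) == 0:
        return out
    both["visit_id"] = vid[both["fix"]]
    both["dwell"] = dt_min[both["fix"]]

    dwell = both.groupby(["visit_id", "poi"], sort=False)["dwell"].sum()
    contacted = dwell[dwell >= min_dwell_min].reset_index()
    if len(contacted) == 0:
        return out
    contacted["tag"] = tags[contacted["poi"]]
    counts = contacted.groupby(["visit_id", "tag"], sort=False).size().unstack(fill_value=0)
    for tag in counts.columns:
        col = f"contacts_{tag}"
        out[col] = out["visit_id"].map(counts[tag]).fillna(0).astype(np.int64)
    return out


def summarize_days(fixes: pd.DataFrame, max_gap_min: float = 5.0) -> pd.DataFrame:
    """Per child and UTC calendar day: recorded minutes and step total.

    Each inter-fix interval contributes ``min(dt, max_gap_min)`` minutes and
    the ending fix's step increment to the day of its ending fix; a child's
    first fix opens no interval and is not counted.
    """
    f = _sorted_fixes(fixes)
    if len(f) == 0:
        return pd.DataFrame(columns=["child_id", "date", "recorded_min", "steps"])
    child = f["child_id"].to_numpy()
    t = _t_ns(f)
    dt_min = np.zeros(len(f))
    dt_min[1:] = np.diff(t) / 60e9
    prev_same = np.zeros(len(f), dtype=bool)
    prev_same[1:] = child[1:] == child[:-1]

    g = pd.DataFrame({
        "child_id": child[prev_same],
        "date": pd.DatetimeIndex(t[prev_same]).normalize().date,
        "recorded_min": np.minimum(dt_min[prev_same], max_gap_min),
        "steps": f["steps"].to_numpy()[prev_same],
    })
    out = g.groupby(["child_id", "date"], sort=True, as_index=False).agg(
        recorded_min=("recorded_min", "sum"), steps=("steps", "sum"))
    return out


def assign_residence(
    fixes: pd.DataFrame,
    precision: int,
    night_window: tuple[int, int] = (0, 6),
    max_gap_min: float = 5.0,
) -> pd.DataFrame:
    """Home cell per child: the geohash with the most night-time recorded minutes.

    Night-time is the [start, end) hour-of-day window (default 00:00-06:00);
    an interval counts as night when its ending fix falls inside the window,
    and contributes ``min(dt, max_gap_min)`` minutes to the ending fix's cell.
    Ties break to the lexicographically smaller code. Children with no
    night-time intervals are omitted (and are excluded from resident
    indicators downstream).
    """
    f = _sorted_fixes(fixes)
    if len(f) == 0:
        return pd.DataFrame(columns=["child_id", "cell", "code"])
    child = f["child_id"].to_numpy()
    t = _t_ns(f)
    cell = geocode.encode_int_arrays(f["lat"].to_numpy(), f["lon"].to_numpy(), precision)
    dt_min = np.zeros(len(f))
    dt_min[1:] = np.diff(t) / 60e9
    prev_same = np.zeros(len(f), dtype=bool)
    prev_same[1:] = child[1:] == child[:-1]

    hour = pd.DatetimeIndex(t).hour.to_numpy()
    lo, hi = night_window
    night = (hour >= lo) & (hour < hi) if lo < hi else (hour >= lo) | (hour < hi)
    sel = prev_same & night
    if not sel.any():
        return pd.DataFrame(columns=["child_id", "cell", "code"])

    g = pd.DataFrame({
        "child_id": child[sel],
        "cell": cell[sel],
        "min": np.minimum(dt_min[sel], max_gap_min),
    }).groupby(["child_id", "cell"], as_index=False)["min"].sum()
    # max minutes, ties to the smallest cell id == lexicographically smallest code
    g = g.sort_values(["child_id", "min", "cell"], ascending=[True, False, True], kind="mergesort")
    top = g.drop_duplicates("child_id", keep="first")[["child_id", "cell"]].reset_index(drop=True)
    top["code"] = geocode.int_to_code(top["cell"].to_numpy(), precision)
    return top
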