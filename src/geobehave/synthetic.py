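"""Synthetic city and child-cohort trajectory generator.

Everything downstream of the raw data is testable against this module: it
emits the exact file formats the pipeline consumes (trajectory CSV, POI
CSV/GeoJSON, school CSV, municipality GeoJSON) from a known generative
model, so parameter-recovery tests have ground truth.

The model. A rectangular city is partitioned into a grid of municipalities;
schools are placed uniformly; POIs per category are drawn from an
inhomogeneous Poisson process, food categories optionally peaked toward a
"downtown" at the city centre. Each child gets a uniform home and attends
the nearest school. A simulated day is home -> school -> (after-school
hangout) -> home, with straight-line walking between anchors. The hangout
location L is uniform within ``hangout_radius_m`` of the school; the child
"visits" a food place with probability sigmoid(alpha_food + beta_food * d)
where d is the number of food POIs within ``density_radius_m`` of L — the
environment->behavior coupling whose recovery the association tests check —
in which case the dwell is snapped to a nearby food POI (similarly for
sports when no food episode fires). Step counts are Poisson around
context-specific rates (sleep/home low, school moderate, walking high) with
per-fix lognormal dispersion; days on/after ``after_start`` multiply the
rates by the child's home municipality's ``activity_shift_after`` factor
(how an intervention or closure enters the model). Fixes are emitted densely
while moving and sparsely while stationary, each dropped independently with
probability ``dropout``; step increments are accumulated across dropped
fixes so totals are preserved.

Fixed seed implies byte-identical outputs; per-stage child generators keep
the city, the cohort roster and the trajectories independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import box

from . import geocode
from .config import CategoryGroupMap
from .errors import ConfigError
from .temporal import Municipality
from .trajectory import _local_xy

M_PER_DEG = 2 * math.pi * geocode.EARTH_RADIUS_M / 360.0

#: POI spatial intensities, points per km^2, by raw category.
DEFAULT_POI_INTENSITIES: dict[str, float] = {
    "fast_food": 1.5,
    "takeaway": 0.8,
    "supermarket": 1.0,
    "grocery": 0.8,
    "restaurant": 3.0,
    "cafe": 1.5,
    "sports_facility": 0.8,
    "gym": 0.5,
    "park": 0.6,
    "playground": 0.6,
}


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    Defaults describe a mid-size city of ~10 x 9 km with 8 municipalities and
    24 schools, 200 children observed for two weeks at a 60-s fix interval
    while moving (300 s while stationary), 10% fix dropout, and a moderate
    positive coupling of after-school place visits to local POI density.
    """

    seed: int = 0
    n_children: int = 200
    n_days: int = 14
    bbox: tuple[float, float, float, float] = (40.58, 22.88, 40.66, 23.00)  # south, west, north, east
    n_schools: int = 24
    muni_grid: tuple[int, int] = (4, 2)
    poi_intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POI_INTENSITIES))
    downtown_peak: float = 3.0       # food-category intensity multiplier at the centre
    downtown_sigma_km: float = 1.5
    alpha_food: float = -1.0
    beta_food: float = 2.0
    alpha_sports: float = -1.5
    beta_sports: float = 2.0
    home_rate: float = 30.0          # steps/hour by context
    school_rate: float = 250.0
    walk_rate: float = 4800.0
    hangout_rate: float = 600.0
    rate_sigma: float = 0.25         # lognormal sigma of the per-fix rate multiplier
    activity_shift_after: dict[str, float] = field(default_factory=dict)
    start_date: date = date(2020, 3, 1)
    after_start: date = date(2020, 3, 11)
    fix_interval_s: int = 60
    stationary_interval_s: int = 300
    dropout: float = 0.1
    hangout_radius_m: float = 800.0
    snap_radius_m: float = 200.0
    density_radius_m: float = 150.0
    walk_speed_ms: float = 1.4
    gps_jitter_m: float = 3.0
    city_name: str = "simcity"

    def __post_init__(self) -> None:
        s, w, n, e = self.bbox
        if not (n > s and e > w):
            raise ConfigError("bbox must have positive area")
        if not 0.0 <= self.dropout <= 1.0:
            raise ConfigError("dropout must be in [0, 1]")
        if any(v < 0 for v in self.poi_intensities.values()):
            raise ConfigError("POI intensities must be non-negative")


@dataclass
class City:
    pois: pd.DataFrame            # id, category, lat, lon
    schools: pd.DataFrame         # id, lat, lon, city
    municipalities: list[Municipality]
    bbox: tuple[float, float, float, float]
    name: str


def _sigmoid(z: float) -> float:
    z = max(-700.0, min(700.0, z))
    return 1.0 / (1.0 + math.exp(-z))


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _area_km2(bbox) -> float:
    s, w, n, e = bbox
    mid = (s + n) / 2.0
    return (n - s) * M_PER_DEG * (e - w) * M_PER_DEG * math.cos(math.radians(mid)) / 1e6


def generate_city(cfg: SimConfig) -> City:
    """Sample POIs and schools; build the deterministic municipality grid."""
    rng = _rng(cfg, 0)
    s, w, n, e = cfg.bbox
    area = _area_km2(cfg.bbox)
    cmap = CategoryGroupMap()
    clat, clon = (s + n) / 2.0, (w + e) / 2.0

    rows = []
    for cat in sorted(cfg.poi_intensities):
        base = cfg.poi_intensities[cat]
        if base == 0:
            continue
        peaked = cmap.group(cat) == "food" and cfg.downtown_peak > 1.0
        lam_max = base * (cfg.downtown_peak if peaked else 1.0)
        n_cand = rng.poisson(lam_max * area)
        lat = rng.uniform(s, n, n_cand)
        lon = rng.uniform(w, e, n_cand)
        if peaked and n_cand:
            d_km = geocode.haversine_m_arrays(lat, lon, clat, clon) / 1000.0
            intensity = base * (1.0 + (cfg.downtown_peak - 1.0) * np.exp(-(d_km ** 2) / (2 * cfg.downtown_sigma_km ** 2)))
            keep = rng.uniform(0, lam_max, n_cand) < intensity
            lat, lon = lat[keep], lon[keep]
        rows.append(pd.DataFrame({"category": cat, "lat": lat, "lon": lon}))
    pois = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["category", "lat", "lon"])
    pois.insert(0, "id", [f"poi_{i}" for i in range(len(pois))])

    schools = pd.DataFrame({
        "id": [f"school_{i}" for i in range(cfg.n_schools)],
        "lat": rng.uniform(s, n, cfg.n_schools),
        "lon": rng.uniform(w, e, cfg.n_schools),
        "city": cfg.city_name,
    })

    nx, ny = cfg.muni_grid
    munis = []
    for iy in range(ny):
        for ix in range(nx):
            poly = box(w + ix * (e - w) / nx, s + iy * (n - s) / ny,
                       w + (ix + 1) * (e - w) / nx, s + (iy + 1) * (n - s) / ny)
            munis.append(Municipality(name=f"muni_{iy * nx + ix + 1}", boundary=poly))
    return City(pois=pois, schools=schools, municipalities=munis, bbox=cfg.bbox, name=cfg.city_name)


def _municipality_of(cfg: SimConfig, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    s, w, n, e = cfg.bbox
    nx, ny = cfg.muni_grid
    ix = np.clip(((lon - w) / (e - w) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((lat - s) / (n - s) * ny).astype(int), 0, ny - 1)
    idx = iy * nx + ix + 1
    return np.array([f"muni_{i}" for i in idx])


def sample_children(cfg: SimConfig, city: City) -> pd.DataFrame:
    """The cohort roster: uniform homes, nearest school, home cell/municipality."""
    rng = _rng(cfg, 1)
    s, w, n, e = cfg.bbox
    lat = rng.uniform(s, n, cfg.n_children)
    lon = rng.uniform(w, e, cfg.n_children)
    mid = (s + n) / 2.0
    hxy = _local_xy(lat, lon, mid, (w + e) / 2.0)
    sxy = _local_xy(city.schools["lat"].to_numpy(), city.schools["lon"].to_numpy(), mid, (w + e) / 2.0)
    school_idx = cKDTree(sxy).query(hxy)[1]
    cells = geocode.encode_int_arrays(lat, lon, 7)
    return pd.DataFrame({
        "child_id": [f"child_{i:04d}" for i in range(cfg.n_children)],
        "home_lat": lat,
        "home_lon": lon,
        "home_cell": geocode.int_to_code(cells, 7),
        "home_muni": _municipality_of(cfg, lat, lon),
        "school_id": city.schools["id"].to_numpy()[school_idx],
        "school_lat": city.schools["lat"].to_numpy()[school_idx],
        "school_lon": city.schools["lon"].to_numpy()[school_idx],
    })


def _walk(t0: float, xy0, xy1, speed: float, interval: int):
    """Times (s) and positions of a straight walk; returns (t, x, y, t_arrive)."""
    dist = float(np.hypot(xy1[0] - xy0[0], xy1[1] - xy0[1]))
    dur = dist / speed
    t = np.arange(t0 + interval, t0 + dur, interval)
    if dur <= 0:
        return np.empty(0), np.empty(0), np.empty(0), t0
    frac = (t - t0) / dur
    x = xy0[0] + frac * (xy1[0] - xy0[0])
    y = xy0[1] + frac * (xy1[1] - xy0[1])
    return t, x, y, t0 + dur


def _stay(t0: float, t1: float, xy, interval: int):
    t = np.arange(t0 + interval, t1, interval)
    return t, np.full(t.size, xy[0]), np.full(t.size, xy[1])


def generate_cohort(cfg: SimConfig, city: City, children: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate the cohort's fixes: ``child_id, t, lat, lon, steps``.

    Rates are in steps/hour; each fix carries the steps accrued since the
    child's previous *emitted* fix (dropout-robust by accumulation).
    """
    rng = _rng(cfg, 2)
    if children is None:
        children = sample_children(cfg, city)
    s, w, n, e = cfg.bbox
    lat0, lon0 = (s + n) / 2.0, (w + e) / 2.0

    cmap = CategoryGroupMap()
    groups = city.pois["category"].map(cmap.group).to_numpy() if len(city.pois) else np.array([])
    pxy_all = _local_xy(city.pois["lat"].to_numpy(), city.pois["lon"].to_numpy(), lat0, lon0) \
        if len(city.pois) else np.empty((0, 2))
    food_xy = pxy_all[groups == "food"] if len(city.pois) else np.empty((0, 2))
    sport_xy = pxy_all[groups == "sports"] if len(city.pois) else np.empty((0, 2))
    food_tree = cKDTree(food_xy) if len(food_xy) else None
    sport_tree = cKDTree(sport_xy) if len(sport_xy) else None

    shift_of = {m.name: float(cfg.activity_shift_after.get(m.name, 1.0)) for m in city.municipalities}

    frames = []
    for child in children.itertuples(index=False):
        home = _local_xy(np.array([child.home_lat]), np.array([child.home_lon]), lat0, lon0)[0]
        school = _local_xy(np.array([child.school_lat]), np.array([child.school_lon]), lat0, lon0)[0]
        t_all, x_all, y_all, rate_all, day_all = [], [], [], [], []

        for d in range(cfg.n_days):
            day = cfg.start_date + timedelta(days=d)
            mult = shift_of.get(child.home_muni, 1.0) if day >= cfg.after_start else 1.0

            def emit(t, x, y, rate):
                if len(t) == 0:
                    return
                t_all.append(t)
                x_all.append(x)
                y_all.append(y)
                rate_all.append(np.full(len(t), rate * mult))
                day_all.append(np.full(len(t), d, dtype=np.int32))

            t_leave = 7 * 3600 + 1800 + float(rng.uniform(-600, 600))
            t, x, y = _stay(0.0, t_leave, home, cfg.stationary_interval_s)
            emit(t, x, y, cfg.home_rate)

            t, x, y, t_arr = _walk(t_leave, home, school, cfg.walk_speed_ms, cfg.fix_interval_s)
            emit(t, x, y, cfg.walk_rate)

            t_out = 14 * 3600 + float(rng.uniform(-900, 900))
            t_out = max(t_out, t_arr + cfg.stationary_interval_s)
            t, x, y = _stay(t_arr, t_out, school, cfg.stationary_interval_s)
            emit(t, x, y, cfg.school_rate)

            # after-school hangout, possibly snapped to a POI (the coupling)
            ang = rng.uniform(0, 2 * math.pi)
            rad = cfg.hangout_radius_m * math.sqrt(rng.uniform())
            L = school + np.array([rad * math.cos(ang), rad * math.sin(ang)])
            target = L
            if food_tree is not None:
                dens = food_tree.query_ball_point(L, cfg.density_radius_m, return_length=True)
                p = _sigmoid(cfg.alpha_food + cfg.beta_food * dens)
                snapped = False
                if rng.uniform() < p:
                    near = food_tree.query_ball_point(L, cfg.snap_radius_m)
                    if near:
                        target = food_xy[near[int(rng.integers(len(near)))]]
                        snapped = True
                if not snapped and sport_tree is not None:
                    dens_s = sport_tree.query_ball_point(L, cfg.density_radius_m, return_length=True)
                    p_s = _sigmoid(cfg.alpha_sports + cfg.beta_sports * dens_s)
                    if rng.uniform() < p_s:
                        near = sport_tree.query_ball_point(L, cfg.snap_radius_m)
                        if near:
                            target = sport_xy[near[int(rng.integers(len(near)))]]

            t, x, y, t_arr = _walk(t_out, school, target, cfg.walk_speed_ms, cfg.fix_interval_s)
            emit(t, x, y, cfg.walk_rate)
            t_end = t_arr + 20 * 60
            t, x, y = _stay(t_arr, t_end, target, cfg.fix_interval_s)
            emit(t, x, y, cfg.hangout_rate)

            t, x, y, t_arr = _walk(t_end, target, home, cfg.walk_speed_ms, cfg.fix_interval_s)
            emit(t, x, y, cfg.walk_rate)
            t, x, y = _stay(t_arr, 24 * 3600 - 1, home, cfg.stationary_interval_s)
            emit(t, x, y, cfg.home_rate)

        t = np.concatenate(t_all)
        x = np.concatenate(x_all)
        y = np.concatenate(y_all)
        rate = np.concatenate(rate_all)
        dayix = np.concatenate(day_all)

        # absolute seconds since start_date midnight; per-fix step increments
        t_abs = dayix.astype(np.float64) * 86400.0 + t
        dt = np.diff(t_abs, prepend=t_abs[0])
        dt[0] = 0.0
        steps = rng.poisson(rate * dt / 3600.0 * rng.lognormal(0.0, cfg.rate_sigma, size=len(t_abs)))
        jitter = rng.normal(0.0, cfg.gps_jitter_m, size=(len(t_abs), 2))
        keep = rng.uniform(size=len(t_abs)) >= cfg.dropout
        if not keep.any():
            continue
        cum = np.cumsum(steps)[keep]
        inc = np.diff(cum, prepend=cum[0])
        inc[0] = 0

        xk = x[keep] + jitter[keep, 0]
        yk = y[keep] + jitter[keep, 1]
        lat = lat0 + yk / M_PER_DEG
        lon = lon0 + xk / (M_PER_DEG * math.cos(math.radians(lat0)))
        frames.append(pd.DataFrame({
            "child_id": child.child_id,
            "t": pd.Timestamp(cfg.start_date, tz="UTC") + pd.to_timedelta(t_abs[keep], unit="s"),
            "lat": lat,
            "lon": lon,
            "steps": inc.astype(np.int64),
        }))
    if not frames:
        return pd.DataFrame(columns=["child_id", "t", "lat", "lon", "steps"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["child_id", "t"], kind="mergesort").reset_index(drop=True)


def ground_truth(cfg: SimConfig, city: City) -> dict[str, pd.DataFrame]:
    """Truth tables for recovery tests.

    ``homes``: the roster with true home cells and municipalities;
    ``cell_counts``: per 7-digit cell, true POI counts by group (direct
    encoding of the sampled layer); ``shifts``: the configured after-period
    step-rate factor per municipality.
    """
    children = sample_children(cfg, city)
    cmap = CategoryGroupMap()
    if len(city.pois):
        codes = geocode.int_to_code(
            geocode.encode_int_arrays(city.pois["lat"].to_numpy(), city.pois["lon"].to_numpy(), 7), 7)
        cc = pd.DataFrame({"code": codes, "group": city.pois["category"].map(cmap.group)})
        cell_counts = cc.groupby(["code", "group"]).size().unstack(fill_value=0).reset_index()
    else:
        cell_counts = pd.DataFrame(columns=["code"])
    shifts = pd.DataFrame({
        "municipality": [m.name for m in city.municipalities],
        "shift": [float(cfg.activity_shift_after.get(m.name, 1.0)) for m in city.municipalities],
    })
    return {"homes": children, "cell_counts": cell_counts, "shifts": shifts}


# ---------------------------------------------------------------- file output

def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.DatetimeIndex(out["t"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out[["child_id", "timestamp", "lat", "lon", "steps"]].to_csv(path, index=False)


def write_city(city: City, outdir) -> dict[str, str]:
    """Write POI CSV, school CSV and municipality GeoJSON; returns the paths."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pois": os.path.join(outdir, "pois.csv"),
        "schools": os.path.join(outdir, "schools.csv"),
        "municipalities": os.path.join(outdir, "municipalities.geojson"),
    }
    city.pois.to_csv(paths["pois"], index=False)
    city.schools.to_csv(paths["schools"], index=False)
    features = []
    for m in city.municipalities:
        features.append({
            "type": "Feature",
            "properties": {"name": m.name},
            "geometry": m.boundary.__geo_interface__,
        })
    with open(paths["municipalities"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return paths
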