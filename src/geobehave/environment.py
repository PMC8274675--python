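"""Environment characteristics of geohash cells from POI layers.

Three characteristic patterns are provided, each instantiated per place
family (tag): the raw POI count inside the cell; the grid density — a 30-m
point lattice is laid over the cell and, for each lattice point, the POIs
within a 100-m radius are counted, the cell's value being the mean over
lattice points (POIs outside the cell but within reach of a lattice point do
count); and the food/sports composites, sums of the per-family counts of the
group.

POI layers are plain tables (``id, category, lat, lon``) from CSV or GeoJSON
point features; categories are resolved to (group, tag) through the
:class:`~geobehave.config.CategoryGroupMap`.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geocode
from .config import ALL_TAGS, CategoryGroupMap
from .errors import InputError
from .trajectory import _local_xy

ENV_COLUMNS = ["region_id", "characteristic", "value"]


def load_pois(path, category_map: CategoryGroupMap) -> pd.DataFrame:
    """Read a POI layer from CSV (``id,category,lat,lon``) or GeoJSON points.

    Adds ``group`` and ``tag`` columns; unknown categories raise ConfigError.
    """
    path = str(path)
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise InputError("POI GeoJSON must contain Point features")
            lon, lat = geom["coordinates"][:2]
            props = feat.get("properties") or {}
            rows.append({"id": props.get("id"), "category": props["category"], "lat": lat, "lon": lon})
        pois = pd.DataFrame(rows, columns=["id", "category", "lat", "lon"])
    else:
        pois = pd.read_csv(path)
        missing = [c for c in ("id", "category", "lat", "lon") if c not in pois.columns]
        if missing:
            raise InputError(f"POI CSV missing columns: {missing}")
    if ((pois["lat"] < -90) | (pois["lat"] > 90) | (pois["lon"] < -180) | (pois["lon"] >= 180)).any():
        raise InputError("POI coordinates out of range")
    pois["group"] = pois["category"].map(category_map.group)
    pois["tag"] = pois["category"].map(category_map.tag)
    return pois


def _tagged(pois: pd.DataFrame, category_map: CategoryGroupMap) -> pd.DataFrame:
    if "tag" not in pois.columns:
        pois = pois.copy()
        pois["group"] = pois["category"].map(category_map.group)
        pois["tag"] = pois["category"].map(category_map.tag)
    return pois


def count_pois_in_cell(pois: pd.DataFrame, cell: str, category_map: CategoryGroupMap, tag: str | None = None) -> float:
    """Number of POIs (of one place family, or all) encoding to ``cell``."""
    if tag is not None and tag not in ALL_TAGS:
        raise InputError(f"unknown place family {tag!r}")
    geocode.decode_geohash(cell)  # validates
    p = _tagged(pois, category_map)
    if tag is not None:
        p = p[p["tag"] == tag]
    if len(p) == 0:
        return 0.0
    codes = geocode.int_to_code(
        geocode.encode_int_arrays(p["lat"].to_numpy(), p["lon"].to_numpy(), len(cell)), len(cell))
    return float((codes == cell).sum())


def _grid_points(cell: geocode.GeohashCell, spacing_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Lattice at ``spacing_m`` pitch anchored at the cell's southwest corner."""
    if spacing_m <= 0:
        raise InputError("grid spacing must be positive")
    mid_lat = (cell.south + cell.north) / 2.0
    m_per_deg = 2 * np.pi * geocode.EARTH_RADIUS_M / 360.0
    dlat = spacing_m / m_per_deg
    dlon = spacing_m / (m_per_deg * np.cos(np.radians(mid_lat)))
    lats = np.arange(cell.south, cell.north, dlat)
    lons = np.arange(cell.west, cell.east, dlon)
    if len(lats) == 0 or len(lons) == 0:
        raise InputError(f"degenerate cell {cell.code!r} for spacing {spacing_m} m")
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    return glat.ravel(), glon.ravel()


def grid_radius_density(
    pois: pd.DataFrame,
    cell: str,
    category_map: CategoryGroupMap,
    tag: str | None = None,
    grid_spacing_m: float = 30.0,
    radius_m: float = 100.0,
) -> float:
    """Mean, over a 30-m lattice inside the cell, of POIs within ``radius_m``."""
    c = geocode.decode_geohash(cell)
    p = _tagged(pois, category_map)
    if tag is not None:
        if tag not in ALL_TAGS:
            raise InputError(f"unknown place family {tag!r}")
        p = p[p["tag"] == tag]
    glat, glon = _grid_points(c, grid_spacing_m)
    if len(p) == 0:
        return 0.0
    lat0 = float(c.center.lat)
    lon0 = float(c.center.lon)
    gxy = _local_xy(glat, glon, lat0, lon0)
    pxy = _local_xy(p["lat"].to_numpy(), p["lon"].to_numpy(), lat0, lon0)
    counts = cKDTree(pxy).query_ball_point(gxy, radius_m, return_length=True)
    return float(np.mean(counts))


def composite_group(env: pd.DataFrame, group: str, category_map: CategoryGroupMap) -> pd.DataFrame:
    """Food/sports composite per cell: sum of the group's per-family counts."""
    tags = category_map.tags_in_group(group)
    wanted = [f"count_{t}" for t in tags]
    part = env[env["characteristic"].isin(wanted)]
    g = part.groupby("region_id", as_index=False)["value"].sum()
    g["characteristic"] = f"{group}_composite"
    return g[ENV_COLUMNS]


def environment_table(
    pois: pd.DataFrame,
    cells: np.ndarray | list,
    category_map: CategoryGroupMap,
    grid_spacing_m: float = 30.0,
    radius_m: float = 100.0,
) -> pd.DataFrame:
    """All characteristics for the given geohash codes (one precision).

    Emits ``count_<tag>`` and ``density_<tag>`` for every place family, an
    any-food ``density_food``, and the ``food_composite``/``sports_composite``
    sums. Returns a long table ``region_id, characteristic, value``.
    """
    codes = np.asarray(sorted(set(map(str, cells))))
    if codes.size == 0:
        return pd.DataFrame(columns=ENV_COLUMNS)
    precisions = {len(c) for c in codes}
    if len(precisions) != 1:
        raise InputError("environment_table requires cells of a single precision")
    precision = precisions.pop()
    p = _tagged(pois, category_map)

    parts: list[pd.DataFrame] = []

    # counts per tag via one vectorised encoding of the layer
    if len(p):
        poi_codes = geocode.int_to_code(
            geocode.encode_int_arrays(p["lat"].to_numpy(), p["lon"].to_numpy(), precision), precision)
    else:
        poi_codes = np.array([], dtype="<U1")
    in_scope = pd.DataFrame({"code": poi_codes, "tag": p["tag"].to_numpy() if len(p) else []})
    counts = in_scope.groupby(["code", "tag"]).size() if len(in_scope) else pd.Series(dtype=np.int64)
    for tag in ALL_TAGS:
        vals = np.zeros(codes.size)
        if len(counts):
            sub = counts.xs(tag, level="tag") if tag in counts.index.get_level_values("tag") else None
            if sub is not None:
                vals = sub.reindex(codes).fillna(0).to_numpy(dtype=float)
        parts.append(pd.DataFrame({"region_id": codes, "characteristic": f"count_{tag}", "value": vals}))

    # grid densities: one lattice over all cells, one KD-tree per tag subset
    all_glat, all_glon, owner = [], [], []
    for i, code in enumerate(codes):
        glat, glon = _grid_points(geocode.decode_geohash(code), grid_spacing_m)
        all_glat.append(glat)
        all_glon.append(glon)
        owner.append(np.full(glat.size, i))
    glat = np.concatenate(all_glat)
    glon = np.concatenate(all_glon)
    owner = np.concatenate(owner)
    lat0 = float(np.mean(glat))
    lon0 = float(np.mean(glon))
    gxy = _local_xy(glat, glon, lat0, lon0)

    def density_for(mask: np.ndarray, name: str) -> pd.DataFrame:
        if mask.sum() == 0:
            per_point = np.zeros(glat.size)
        else:
            pxy = _local_xy(p["lat"].to_numpy()[mask], p["lon"].to_numpy()[mask], lat0, lon0)
            per_point = cKDTree(pxy).query_ball_point(gxy, radius_m, return_length=True).astype(float)
        means = pd.DataFrame({"i": owner, "c": per_point}).groupby("i")["c"].mean()
        return pd.DataFrame({"region_id": codes[means.index.to_numpy()],
                             "characteristic": name, "value": means.to_numpy()})

    tags_arr = p["tag"].to_numpy() if len(p) else np.array([])
    group_arr = p["group"].to_numpy() if len(p) else np.array([])
    for tag in ALL_TAGS:
        parts.append(density_for(tags_arr == tag, f"density_{tag}"))
    parts.append(density_for(group_arr == "food", "density_food"))

    env = pd.concat(parts, ignore_index=True)
    env = pd.concat([env, composite_group(env, "food", category_map),
                     composite_group(env, "sports", category_map)], ignore_index=True)
    return env.reset_index(drop=True)
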