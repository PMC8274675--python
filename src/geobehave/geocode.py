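"""Geohash encoding/decoding, cell geometry and geodesic helpers.

The geohash is the standard public base-32 variant: latitude and longitude
are bisected alternately, longitude first, and the resulting bit string is
read off in 5-bit groups against the alphabet ``0123456789bcdefghjkmnpqrstuvwxyz``.
Cells nest: the first k characters of a point's code at precision p > k are
exactly its code at precision k.

Internally the pipeline works with integer cell ids (the interleaved bits at
a fixed precision) because grouping millions of fixes by ``uint64`` is much
cheaper than by string; codes are materialised only at the I/O boundary.

All geodesic quantities use a spherical Earth of radius 6,371,000 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import InputError

EARTH_RADIUS_M = 6_371_000.0

BASE32 = "0123456789bcdefghjkmnpqrstuvwxyz"
_BASE32_INDEX = {c: i for i, c in enumerate(BASE32)}
_BASE32_ARR = np.array(list(BASE32), dtype="<U1")


@dataclass(frozen=True)
class GeoPoint:
    """A WGS-ish latitude/longitude pair in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise InputError(f"non-finite coordinates ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise InputError(f"latitude {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon < 180.0:
            raise InputError(f"longitude {self.lon} out of [-180, 180)")


@dataclass(frozen=True)
class GeohashCell:
    """A decoded geohash: its bounding box and centre."""

    code: str
    precision: int
    south: float
    west: float
    north: float
    east: float

    @property
    def center(self) -> GeoPoint:
        return GeoPoint((self.south + self.north) / 2.0, (self.west + self.east) / 2.0)


def _check_precision(precision: int) -> None:
    if not isinstance(precision, (int, np.integer)) or not 1 <= precision <= 12:
        raise InputError(f"geohash precision must be an integer in 1..12, got {precision!r}")


def _quantize(x: np.ndarray, lo: float, span: float, nbits: int) -> np.ndarray:
    """Exact cell index along one axis: floor((x - lo) / (span / 2**nbits)).

    The naive float expression misassigns points within an ulp of a cell
    edge (e.g. a tiny negative longitude rounding onto the meridian), so the
    candidate index is corrected against the exact edge positions, which are
    representable doubles (span is 45 * 2**k times a power of two).
    """
    w = span / (1 << nbits)  # exact
    q = np.floor((x - lo) / span * (1 << nbits)).astype(np.int64)
    np.clip(q, 0, (1 << nbits) - 1, out=q)
    edge = lo + q * w        # exact multiples of w
    q -= (x < edge)
    q += (x >= edge + w)
    np.clip(q, 0, (1 << nbits) - 1, out=q)
    return q.astype(np.uint64)


def encode_int_arrays(lat: np.ndarray, lon: np.ndarray, precision: int) -> np.ndarray:
    """Vectorised geohash encoding to interleaved-bit integers.

    Returns a uint64 array; the 5*precision interleaved bits, longitude bit
    first at the most significant position. ``int_to_code`` turns these into
    base-32 strings.
    """
    _check_precision(precision)
    lat = np.asarray(lat, dtype=np.float64)
    lon = np.asarray(lon, dtype=np.float64)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise InputError("non-finite coordinates")
    if np.any(lat < -90) or np.any(lat > 90) or np.any(lon < -180) or np.any(lon >= 180):
        raise InputError("coordinates out of range")

    nbits = 5 * precision
    n_lon = (nbits + 1) // 2
    n_lat = nbits // 2
    lon_q = _quantize(lon, -180.0, 360.0, n_lon)
    lat_q = _quantize(lat, -90.0, 180.0, n_lat)

    out = np.zeros(lat.shape, dtype=np.uint64)
    for k in range(nbits):  # k = 0 is the most significant (first) bit: longitude
        if k % 2 == 0:
            bit = (lon_q >> np.uint64(n_lon - 1 - k // 2)) & np.uint64(1)
        else:
            bit = (lat_q >> np.uint64(n_lat - 1 - k // 2)) & np.uint64(1)
        out |= bit << np.uint64(nbits - 1 - k)
    return out


def int_to_code(cells: np.ndarray, precision: int) -> np.ndarray:
    """Turn interleaved-bit integers into base-32 geohash strings (vectorised)."""
    _check_precision(precision)
    cells = np.asarray(cells, dtype=np.uint64).ravel()
    idx = np.empty((cells.size, precision), dtype=np.int64)
    for j in range(precision):
        idx[:, j] = ((cells >> np.uint64(5 * (precision - 1 - j))) & np.uint64(31)).astype(np.int64)
    chars = _BASE32_ARR[idx]
    return np.ascontiguousarray(chars).view(f"<U{precision}").ravel()


def code_to_int(code: str) -> int:
    bits = 0
    for c in code:
        if c not in _BASE32_INDEX:
            raise InputError(f"invalid geohash character {c!r} in {code!r}")
        bits = (bits << 5) | _BASE32_INDEX[c]
    return bits


def encode_geohash(p: GeoPoint, precision: int) -> str:
    """Standard base-32 geohash of ``p`` at the given code length."""
    return str(int_to_code(encode_int_arrays(np.array([p.lat]), np.array([p.lon]), precision), precision)[0])


def decode_geohash(code: str) -> GeohashCell:
    """Decode a geohash into its bounding box.

    The box is half-open in spirit ([south, north) x [west, east)): a point on
    the shared edge of two cells encodes into exactly one of them.
    """
    if not isinstance(code, str) or len(code) == 0:
        raise InputError("geohash code must be a non-empty string")
    if len(code) > 12:
        raise InputError(f"geohash code longer than 12 characters: {code!r}")
    lat_lo, lat_hi = -90.0, 90.0
    lon_lo, lon_hi = -180.0, 180.0
    is_lon = True
    for c in code:
        if c not in _BASE32_INDEX:
            raise InputError(f"invalid geohash character {c!r} in {code!r}")
        val = _BASE32_INDEX[c]
        for shift in range(4, -1, -1):
            bit = (val >> shift) & 1
            if is_lon:
                mid = (lon_lo + lon_hi) / 2.0
                if bit:
                    lon_lo = mid
                else:
                    lon_hi = mid
            else:
                mid = (lat_lo + lat_hi) / 2.0
                if bit:
                    lat_lo = mid
                else:
                    lat_hi = mid
            is_lon = not is_lon
    return GeohashCell(code=code, precision=len(code), south=lat_lo, west=lon_lo, north=lat_hi, east=lon_hi)


def cell_center_arrays(cells: np.ndarray, precision: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cell-centre (lat, lon) for interleaved-bit cell ids."""
    _check_precision(precision)
    cells = np.asarray(cells, dtype=np.uint64)
    nbits = 5 * precision
    n_lon = (nbits + 1) // 2
    n_lat = nbits // 2
    lon_q = np.zeros(cells.shape, dtype=np.uint64)
    lat_q = np.zeros(cells.shape, dtype=np.uint64)
    for k in range(nbits):
        bit = (cells >> np.uint64(nbits - 1 - k)) & np.uint64(1)
        if k % 2 == 0:
            lon_q |= bit << np.uint64(n_lon - 1 - k // 2)
        else:
            lat_q |= bit << np.uint64(n_lat - 1 - k // 2)
    lon_w = 360.0 / (1 << n_lon)
    lat_w = 180.0 / (1 << n_lat)
    lon = -180.0 + (lon_q.astype(np.float64) + 0.5) * lon_w
    lat = -90.0 + (lat_q.astype(np.float64) + 0.5) * lat_w
    return lat, lon


def cell_dimensions(code: str) -> tuple[float, float]:
    """(width_m, height_m) of a geohash cell.

    Width is the great-circle length of the east-west box edge measured along
    the cell's mid-latitude parallel; height is the meridian segment between
    the south and north edges. A 6-character cell on the equator comes out at
    roughly 1.22 km x 610 m, a 7-character cell at roughly 153 m x 153 m, and
    width shrinks as cos(latitude) away from the equator.
    """
    cell = decode_geohash(code)
    mid_lat = (cell.south + cell.north) / 2.0
    mid_lon = (cell.west + cell.east) / 2.0
    width = float(haversine_m_arrays(mid_lat, cell.west, mid_lat, cell.east)[()])
    height = float(haversine_m_arrays(cell.south, mid_lon, cell.north, mid_lon)[()])
    return width, height


def haversine_m(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in metres on a sphere of radius 6,371 km."""
    return float(haversine_m_arrays(np.array([a.lat]), np.array([a.lon]), np.array([b.lat]), np.array([b.lon]))[0])


def haversine_m_arrays(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=np.float64)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.minimum(h, 1.0)))


def _validate_ring(ring: Sequence[Sequence[float]]) -> list[tuple[float, float]]:
    pts = [(float(x), float(y)) for x, y in ring]
    if pts and pts[0] == pts[-1]:
        pts = pts[:-1]
    if len(set(pts)) < 3:
        raise InputError("polygon ring needs at least 3 distinct vertices")
    return pts


def point_in_polygon(p: GeoPoint, shell: Sequence[Sequence[float]], holes: Sequence[Sequence[Sequence[float]]] = ()) -> bool:
    """Even-odd containment of a lon/lat point in a ring with optional holes.

    Rings are sequences of (lon, lat) pairs, closed or auto-closed. Points on
    the boundary count as inside; points inside a hole do not.
    """
    shell_pts = _validate_ring(shell)
    hole_pts = [_validate_ring(h) for h in holes]
    poly = Polygon(shell_pts, hole_pts)
    return bool(poly.covers(Point(p.lon, p.lat)))
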