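"""Before/after comparison of a behavior at municipality level.

A behavior (by default steps/hour) is aggregated per 7-digit geohash within
each calendar-date period, a cell contributing whenever at least one user's
behavior was observed there in the period (note: *one* user, not the
dashboard's more-than-5 publication rule — this analysis feeds an
intervention evaluation, not a public map). Each municipality's sample is
the vector of its cells' values, cells being assigned to the first
municipality in the configuration whose boundary covers the cell centre
(border cells are never double-counted). The before and after samples are
compared with Welch's unequal-variance two-sample t test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import shape

from . import geocode, indicators
from .config import PeriodSpec
from .errors import ConfigError, DegenerateDataError, InputError, InsufficientDataError

RESULT_COLUMNS = ["municipality", "n_cells_before", "mean_before", "n_cells_after",
                  "mean_after", "t", "df", "p", "flag"]


@dataclass(frozen=True)
class Municipality:
    name: str
    boundary: object  # shapely Polygon/MultiPolygon


def load_municipalities(path) -> list[Municipality]:
    """GeoJSON FeatureCollection of (Multi)Polygons with a ``name`` property."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise InputError(f"municipality geometry must be (Multi)Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise InputError(f"invalid municipality polygon {feat.get('properties', {}).get('name')!r}")
        out.append(Municipality(name=str((feat.get("properties") or {}).get("name", f"m{len(out)}")), boundary=geom))
    return out


def cells_in_municipality(cells, m: Municipality, precision: int = 7) -> np.ndarray:
    """Cells whose centre lies inside (or on the boundary of) the municipality."""
    codes = np.asarray(sorted(set(map(str, cells))))
    if codes.size == 0:
        return codes
    if any(len(c) != precision for c in codes):
        raise InputError(f"municipality assignment expects precision-{precision} cells")
    ints = np.array([geocode.code_to_int(c) for c in codes], dtype=np.uint64)
    clat, clon = geocode.cell_center_arrays(ints, precision)
    pts = shapely.points(clon, clat)
    return codes[shapely.covers(m.boundary, pts)]


def assign_cells(cells, municipalities: list[Municipality], precision: int = 7) -> pd.Series:
    """Unique cell -> municipality-name assignment, first-in-config precedence."""
    codes = np.asarray(sorted(set(map(str, cells))))
    assigned = pd.Series(index=codes, dtype=object)
    for m in municipalities:
        inside = cells_in_municipality(codes, m, precision)
        mask = assigned.loc[inside].isna()
        assigned.loc[inside[mask.to_numpy()]] = m.name
    return assigned.dropna()


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test: ``(t, df, p)``.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with the
    Welch-Satterthwaite degrees of freedom; two-sided p. Requires at least
    two values per sample and non-zero variance in at least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError(f"welch_t_test needs >= 2 values per sample, got {na} and {nb}")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise DegenerateDataError("both samples have zero variance")
    se2 = va / na + vb / nb
    t = (float(a.mean()) - float(b.mean())) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return float(t), float(df), p


def student_t_test(a, b) -> tuple[float, float, float]:
    """Pooled-variance Student alternative to :func:`welch_t_test`."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError("student_t_test needs >= 2 values per sample")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise DegenerateDataError("both samples have zero variance")
    t = (float(a.mean()) - float(b.mean())) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return float(t), float(df), p


def municipal_series(
    visits: pd.DataFrame,
    period: PeriodSpec,
    basis: str = "visitors",
    min_visit_min: float = 1.0,
    min_support: int = 1,
) -> pd.DataFrame:
    """Per-cell steps/hour within one period: columns ``code, value, n_users``.

    A visit belongs to the period when its entry timestamp's date falls in
    the inclusive [start, end] window; cells with fewer than ``min_support``
    unique users are dropped.
    """
    if len(visits) == 0:
        return pd.DataFrame(columns=["code", "value", "n_users"])
    dates = pd.DatetimeIndex(visits["t_entry"]).date
    v = visits[(dates >= period.start) & (dates <= period.end)]
    if basis == "visitors":
        table = indicators.steps_per_hour_by_visitors(v, min_visit_min)
    elif basis == "visits":
        table = indicators.steps_per_hour_by_visits(v, min_visit_min)
    else:
        raise ConfigError(f"unknown basis {basis!r}")
    users = v.groupby("code")["child_id"].nunique() if len(v) else pd.Series(dtype=np.int64)
    out = table.rename(columns={"region_id": "code"})[["code", "value"]]
    out["n_users"] = out["code"].map(users).fillna(0).astype(np.int64)
    return out[out["n_users"] >= min_support].reset_index(drop=True)


def compare_periods(
    visits: pd.DataFrame,
    municipalities: list[Municipality],
    before: PeriodSpec,
    after: PeriodSpec,
    basis: str = "visitors",
    precision: int = 7,
    min_visit_min: float = 1.0,
    min_support: int = 1,
    test: str = "welch",
) -> pd.DataFrame:
    """Municipality-level before/after comparison, plus a pooled Total row.

    One row per municipality: per-period cell counts, the unweighted mean of
    the cells' steps/hour, and the two-sided t-test p-value. Municipalities
    where the test is undefined are flagged (``insufficient_n`` /
    ``zero_variance``), never silently dropped.
    """
    if before.overlaps(after):
        raise ConfigError("before and after periods overlap")
    tester = welch_t_test if test == "welch" else student_t_test
    sb = municipal_series(visits, before, basis, min_visit_min, min_support)
    sa = municipal_series(visits, after, basis, min_visit_min, min_support)
    assignment = assign_cells(pd.concat([sb["code"], sa["code"]]).unique(), municipalities, precision)

    rows = []
    pooled_a, pooled_b = [], []
    for m in municipalities:
        cells_m = assignment[assignment == m.name].index
        a = sb[sb["code"].isin(cells_m)]["value"].to_numpy()
        b = sa[sa["code"].isin(cells_m)]["value"].to_numpy()
        pooled_b.append(a)
        pooled_a.append(b)
        rows.append(_compare_row(m.name, a, b, tester))
    rows.append(_compare_row("Total", np.concatenate(pooled_b) if pooled_b else np.empty(0),
                             np.concatenate(pooled_a) if pooled_a else np.empty(0), tester))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _compare_row(name: str, a: np.ndarray, b: np.ndarray, tester) -> dict:
    row = {
        "municipality": name,
        "n_cells_before": int(a.size),
        "mean_before": float(a.mean()) if a.size else np.nan,
        "n_cells_after": int(b.size),
        "mean_after": float(b.mean()) if b.size else np.nan,
        "t": np.nan, "df": np.nan, "p": np.nan, "flag": "",
    }
    try:
        t, df, p = tester(a, b)
        row.update(t=t, df=df, p=p)
    except InsufficientDataError:
        row["flag"] = "insufficient_n"
    except DegenerateDataError:
        row["flag"] = "zero_variance"
    return row
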