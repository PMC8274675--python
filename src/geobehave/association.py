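"""Behavior x environment correlations in school-proximal geohashes.

The analysis joins the suppression-filtered indicator table with the
environment table over the 7-digit geohashes whose centre lies strictly
within 1000 m of a school, separately for each city (per-city stratification
guards against between-city confounding), and computes the Pearson
correlation r = cov(X, Y) / (sigma_X * sigma_Y) for each configured
behavior-characteristic pair, with a two-sided p-value from
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom and a 95% CI from
the Fisher z-transform, tanh(atanh r +/- z_0.975 / sqrt(n-3)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import geocode
from .errors import DegenerateDataError, InputError, InsufficientDataError

#: Default behavior-characteristic pairs: step rates against the food and
#: sports composites on both bases, and each visit-percentage against the
#: density of its own place family.
DEFAULT_PAIRINGS: tuple[tuple[str, str, str], ...] = (
    ("steps_per_hour", "visitors", "food_composite"),
    ("steps_per_hour", "visitors", "sports_composite"),
    ("steps_per_hour", "visits", "food_composite"),
    ("steps_per_hour", "visits", "sports_composite"),
    ("pct_visits_food", "visits", "density_food"),
    ("pct_visits_fast_food_takeaway", "visits", "density_fast_food_takeaway"),
    ("pct_visits_supermarket_grocery", "visits", "density_supermarket_grocery"),
    ("pct_visits_sports_facility", "visits", "density_sports_facility"),
    ("pct_visits_indoor_recreation", "visits", "density_indoor_recreation"),
    ("pct_visits_park", "visits", "density_park"),
)

RESULT_COLUMNS = ["city", "behavior", "basis", "characteristic", "n", "r", "ci_low", "ci_high", "p", "flag"]


@dataclass(frozen=True)
class SchoolSite:
    id: str
    lat: float
    lon: float
    city: str = ""


def load_schools(path) -> pd.DataFrame:
    schools = pd.read_csv(path)
    missing = [c for c in ("id", "lat", "lon") if c not in schools.columns]
    if missing:
        raise InputError(f"school CSV missing columns: {missing}")
    if "city" not in schools.columns:
        schools["city"] = ""
    return schools


def select_school_geohashes(cells, schools: pd.DataFrame, radius_m: float = 1000.0, precision: int = 7) -> np.ndarray:
    """Cells whose centre lies strictly within ``radius_m`` of any school.

    ``cells`` are geohash codes at ``precision`` (the analysis uses 7-digit
    cells); the output is deduplicated and sorted.
    """
    codes = np.asarray(sorted(set(map(str, cells))))
    if codes.size == 0:
        return codes
    if any(len(c) != precision for c in codes):
        raise InputError(f"school-proximity selection expects precision-{precision} cells")
    ints = np.array([geocode.code_to_int(c) for c in codes], dtype=np.uint64)
    clat, clon = geocode.cell_center_arrays(ints, precision)
    keep = np.zeros(codes.size, dtype=bool)
    for _, s in schools.iterrows():
        d = geocode.haversine_m_arrays(clat, clon, float(s["lat"]), float(s["lon"]))
        keep |= d < radius_m
    return codes[keep]


def pearson(x, y) -> tuple[float, float, float, float]:
    """Pearson r with 95% Fisher-z CI and two-sided t-test p-value.

    Returns ``(r, ci_low, ci_high, p)``. Sample (n-1) covariance throughout;
    requires n >= 3 and non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson expects two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"pearson needs n >= 3, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateDataError("correlation undefined: zero variance")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))

    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        ci_low, ci_high = (-1.0, 1.0) if abs(r) < 1.0 else (r, r)
    return r, ci_low, ci_high, p


def associate(
    indicator_table: pd.DataFrame,
    env_table: pd.DataFrame,
    schools: pd.DataFrame,
    pairings=DEFAULT_PAIRINGS,
    radius_m: float = 1000.0,
    precision: int = 7,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-city correlation table for each behavior-characteristic pair.

    Joins both tables on school-proximal cells where both values exist.
    Pairs with fewer than 3 joined cells or a constant vector are kept with a
    ``flag`` (``insufficient_n`` / ``zero_variance``) rather than dropped.
    When ``bh_correct`` is set, a Benjamini-Hochberg adjusted ``p_adj``
    column is added (off by default: raw per-pair p-values are reported).
    """
    rows = []
    cities = sorted(set(schools["city"].astype(str)))
    for city in cities:
        city_schools = schools[schools["city"].astype(str) == city]
        cells = select_school_geohashes(indicator_table["region_id"].unique(), city_schools, radius_m, precision)
        env_wide = env_table.pivot_table(index="region_id", columns="characteristic", values="value")
        for behavior, basis, characteristic in pairings:
            ind = indicator_table[
                (indicator_table["indicator"] == behavior)
                & (indicator_table["basis"] == basis)
                & (indicator_table["region_id"].isin(cells))
            ]
            row = {"city": city, "behavior": behavior, "basis": basis,
                   "characteristic": characteristic, "n": 0, "r": np.nan,
                   "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "flag": ""}
            if characteristic not in env_wide.columns or len(ind) == 0:
                row["flag"] = "insufficient_n"
                rows.append(row)
                continue
            joined = ind.merge(
                env_wide[characteristic].rename("env"), left_on="region_id", right_index=True, how="inner"
            ).dropna(subset=["value", "env"])
            row["n"] = len(joined)
            try:
                r, lo, hi, p = pearson(joined["value"].to_numpy(), joined["env"].to_numpy())
                row.update(r=r, ci_low=lo, ci_high=hi, p=p)
            except InsufficientDataError:
                row["flag"] = "insufficient_n"
            except DegenerateDataError:
                row["flag"] = "zero_variance"
            rows.append(row)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if bh_correct:
        out["p_adj"] = np.nan
        ok = out["p"].notna()
        if ok.any():
            out.loc[ok, "p_adj"] = stats.false_discovery_control(out.loc[ok, "p"].to_numpy(), method="bh")
    return out
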