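import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geobehave import association as asc
from geobehave import geocode as gc
from geobehave.errors import DegenerateDataError, InputError, InsufficientDataError


def pearson_oracle(x, y):
    """Direct textbook evaluation: r = cov/(sx sy), t-based p, Fisher z CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    cov = np.sum((x - x.mean()) * (y - y.mean())) / (n - 1)
    r = cov / (np.std(x, ddof=1) * np.std(y, ddof=1))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
    lo, hi = math.tanh(math.atanh(r) - half), math.tanh(math.atanh(r) + half)
    return r, lo, hi, p


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, lo, hi, p = asc.pearson(x, x)
        assert r == 1.0 and p == 0.0

    def test_perfect_negative(self):
        r, _, _, _ = asc.pearson([1, 2, 3], [3, 2, 1])
        assert r == -1.0

    def test_five_point_example_matches_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r, lo, hi, p = asc.pearson(x, y)
        er, elo, ehi, ep = pearson_oracle(x, y)
        assert abs(r - er) < 1e-12 and abs(p - ep) < 1e-12
        assert abs(lo - elo) < 1e-12 and abs(hi - ehi) < 1e-12

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, _, _, p = asc.pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_ci_brackets_r_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            r, lo, hi, p = asc.pearson(rng.normal(size=n), rng.normal(size=n))
            assert -1 <= lo <= r <= hi <= 1
            assert 0 <= p <= 1

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = asc.pearson(x, y)[0]
        assert asc.pearson(3.2 * x + 7, y)[0] == pytest.approx(r0, abs=1e-12)
        assert asc.pearson(-2.0 * x, y)[0] == pytest.approx(-r0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            asc.pearson([1, 2], [3, 4])
        with pytest.raises(DegenerateDataError):
            asc.pearson([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(InputError):
            asc.pearson([1, 2, 3], [1, 2])

    def test_type_one_error_calibrated_under_null(self):
        """Independent normal x, y at n=50: P(p < .05) = .05 (10k replicates)."""
        rng = np.random.default_rng(123)
        reps, n = 10_000, 50
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        frac = float((p < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.01)
        # spot-check the vectorised null against the implementation
        for i in range(5):
            ri, _, _, pi = asc.pearson(x[i], y[i])
            assert ri == pytest.approx(r[i], abs=1e-12) and pi == pytest.approx(p[i], abs=1e-12)


SCHOOL_LAT, SCHOOL_LON = 40.6401, 22.9444


def cells_around(lat, lon, dlat_steps, precision=7):
    """Codes of cells at given multiples of a cell-height north of (lat, lon)."""
    h = gc.decode_geohash(gc.encode_geohash(gc.GeoPoint(lat, lon), precision))
    height = h.north - h.south
    return [gc.encode_geohash(gc.GeoPoint(lat + k * height, lon), precision) for k in dlat_steps]


class TestSelectSchoolGeohashes:
    schools = pd.DataFrame({"id": ["s1"], "lat": [SCHOOL_LAT], "lon": [SCHOOL_LON], "city": ["x"]})

    def test_cell_at_school_included(self):
        code = gc.encode_geohash(gc.GeoPoint(SCHOOL_LAT, SCHOOL_LON), 7)
        assert code in asc.select_school_geohashes([code], self.schools)

    def test_strict_1000m_boundary(self):
        near = gc.encode_geohash(gc.GeoPoint(SCHOOL_LAT + 900 / 111000, SCHOOL_LON), 7)
        far = gc.encode_geohash(gc.GeoPoint(SCHOOL_LAT + 1300 / 111000, SCHOOL_LON), 7)
        out = asc.select_school_geohashes([near, far], self.schools)
        assert near in out and far not in out
        # the far cell centre is beyond 1000 m from every school
        c = gc.decode_geohash(far).center
        assert gc.haversine_m(c, gc.GeoPoint(SCHOOL_LAT, SCHOOL_LON)) > 1000

    def test_deduplicated_near_two_schools(self):
        two = pd.DataFrame({"id": ["s1", "s2"], "lat": [SCHOOL_LAT, SCHOOL_LAT],
                            "lon": [SCHOOL_LON, SCHOOL_LON + 0.001], "city": ["x", "x"]})
        code = gc.encode_geohash(gc.GeoPoint(SCHOOL_LAT, SCHOOL_LON), 7)
        out = asc.select_school_geohashes([code, code], two)
        assert list(out).count(code) == 1

    def test_subset_and_radius_monotonicity(self):
        cells = cells_around(SCHOOL_LAT, SCHOOL_LON, range(0, 30, 3))
        small = set(asc.select_school_geohashes(cells, self.schools, radius_m=500))
        large = set(asc.select_school_geohashes(cells, self.schools, radius_m=2000))
        assert small <= large <= set(cells)

    def test_wrong_precision_rejected(self):
        with pytest.raises(InputError):
            asc.select_school_geohashes(["u4pruy"], self.schools, precision=7)


def tables_for(codes, behavior_vals, env_vals, characteristic="food_composite"):
    ind = pd.DataFrame({"region_id": codes, "indicator": "steps_per_hour", "basis": "visits",
                        "value": behavior_vals, "n_contributors": 9})
    env = pd.DataFrame({"region_id": codes, "characteristic": characteristic, "value": env_vals})
    return ind, env


class TestAssociate:
    def test_constant_env_flagged(self):
        codes = cells_around(SCHOOL_LAT, SCHOOL_LON, range(5))
        ind, env = tables_for(codes, [1.0, 2, 3, 4, 5], [7.0] * 5)
        schools = pd.DataFrame({"id": ["s"], "lat": [SCHOOL_LAT], "lon": [SCHOOL_LON], "city": ["x"]})
        out = asc.associate(ind, env, schools, pairings=[("steps_per_hour", "visits", "food_composite")])
        assert out.iloc[0]["flag"] == "zero_variance" and out.iloc[0]["n"] == 5

    def test_insufficient_cells_flagged(self):
        codes = cells_around(SCHOOL_LAT, SCHOOL_LON, range(2))
        ind, env = tables_for(codes, [1.0, 2.0], [1.0, 2.0])
        schools = pd.DataFrame({"id": ["s"], "lat": [SCHOOL_LAT], "lon": [SCHOOL_LON], "city": ["x"]})
        out = asc.associate(ind, env, schools, pairings=[("steps_per_hour", "visits", "food_composite")])
        assert out.iloc[0]["flag"] == "insufficient_n"

    def test_per_city_stratification_beats_pooling(self):
        """Simpson-style construction: negative within each city, positive pooled."""
        lat2 = SCHOOL_LAT + 0.5
        codes1 = cells_around(SCHOOL_LAT, SCHOOL_LON, range(5))
        codes2 = cells_around(lat2, SCHOOL_LON, range(5))
        x1 = np.array([0, 1, 2, 3, 4.0])
        y1 = 5 - x1           # city 1: negative association, low levels
        x2 = x1 + 20
        y2 = 25 - x1          # city 2: negative association, high levels
        ind, env = tables_for(codes1 + codes2, np.r_[x1, x2], np.r_[y1, y2])
        schools = pd.DataFrame({"id": ["s1", "s2"], "lat": [SCHOOL_LAT, lat2],
                                "lon": [SCHOOL_LON] * 2, "city": ["one", "two"]})
        out = asc.associate(ind, env, schools, pairings=[("steps_per_hour", "visits", "food_composite")])
        assert set(out["city"]) == {"one", "two"}
        assert (out["r"] < -0.99).all()
        pooled = asc.pearson(np.r_[x1, x2], np.r_[y1, y2])[0]
        assert pooled > 0  # pooling would reverse the sign

    def test_bh_option_adds_adjusted_column(self):
        codes = cells_around(SCHOOL_LAT, SCHOOL_LON, range(8))
        rng = np.random.default_rng(4)
        ind, env = tables_for(codes, rng.normal(size=8), rng.normal(size=8))
        schools = pd.DataFrame({"id": ["s"], "lat": [SCHOOL_LAT], "lon": [SCHOOL_LON], "city": ["x"]})
        out = asc.associate(ind, env, schools, pairings=[("steps_per_hour", "visits", "food_composite")],
                            bh_correct=True)
        assert "p_adj" in out.columns
        assert out["p_adj"].iloc[0] >= out["p"].iloc[0]
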