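import io

import numpy as np
import pandas as pd
import pytest

from geobehave import geocode as gc
from geobehave import trajectory as tj
from geobehave.config import CategoryGroupMap
from geobehave.errors import InputError
from tests.conftest import make_fixes

# two points ~2 km apart -> always different precision-7 cells
LAT_A, LON_A = 40.6401, 22.9444
LAT_B, LON_B = 40.6601, 22.9444
CODE_A = gc.encode_geohash(gc.GeoPoint(LAT_A, LON_A), 7)


class TestLoadFixes:
    def test_empty_file(self):
        out = tj.load_fixes(io.StringIO("child_id,timestamp,lat,lon,steps\n"))
        assert len(out) == 0

    def test_three_rows_sorted(self):
        csv = (
            "child_id,timestamp,lat,lon,steps\n"
            "c1,2020-03-01T10:02:00Z,40.64,22.94,5\n"
            "c1,2020-03-01T10:00:00Z,40.64,22.94,0\n"
            "c1,2020-03-01T10:01:00Z,40.64,22.94,3\n"
        )
        out = tj.load_fixes(io.StringIO(csv))
        assert list(out["steps"]) == [0, 3, 5]
        assert out["t"].is_monotonic_increasing

    def test_bad_latitude_names_line(self):
        csv = (
            "child_id,timestamp,lat,lon,steps\n"
            "c1,2020-03-01T10:00:00Z,40.64,22.94,0\n"
            "c1,2020-03-01T10:01:00Z,95.0,22.94,3\n"
        )
        with pytest.raises(InputError, match="line 3"):
            tj.load_fixes(io.StringIO(csv), strict=True)
        lenient = tj.load_fixes(io.StringIO(csv), strict=False)
        assert len(lenient) == 1

    def test_duplicate_timestamp_rejected(self):
        csv = (
            "child_id,timestamp,lat,lon,steps\n"
            "c1,2020-03-01T10:00:00Z,40.64,22.94,0\n"
            "c1,2020-03-01T10:00:00Z,40.64,22.94,3\n"
        )
        with pytest.raises(InputError):
            tj.load_fixes(io.StringIO(csv), strict=True)

    def test_missing_column(self):
        with pytest.raises(InputError, match="missing columns"):
            tj.load_fixes(io.StringIO("child_id,timestamp,lat,lon\nc1,2020-03-01,1,1\n"))


class TestSegmentVisits:
    def test_single_fix_no_visit(self):
        fixes = make_fixes([("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0)])
        visits, fvid, stats = tj.segment_visits(fixes, 7)
        assert len(visits) == 0 and stats["candidates"] == 1

    def test_sub_minute_stay_dropped(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T10:00:30Z", LAT_A, LON_A, 10),
        ])
        visits, _, _ = tj.segment_visits(fixes, 7, min_duration_min=1.0)
        assert len(visits) == 0

    def test_two_minute_stay_steps_after_entry(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 99),  # entry fix steps excluded
            ("c1", "2020-03-01T10:01:00Z", LAT_A, LON_A, 10),
            ("c1", "2020-03-01T10:02:00Z", LAT_A, LON_A, 20),
        ])
        visits, fvid, _ = tj.segment_visits(fixes, 7, min_duration_min=1.0)
        assert len(visits) == 1
        v = visits.iloc[0]
        assert v["steps"] == 30 and v["duration_min"] == 2.0 and v["code"] == CODE_A
        assert list(fvid) == [0, 0, 0]

    def test_gap_splits_run(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T10:02:00Z", LAT_A, LON_A, 10),
            ("c1", "2020-03-01T10:30:00Z", LAT_A, LON_A, 10),  # 28-min gap
            ("c1", "2020-03-01T10:32:00Z", LAT_A, LON_A, 10),
        ])
        visits, _, stats = tj.segment_visits(fixes, 7, max_gap_min=5.0)
        assert len(visits) == 2 and stats["gap_splits"] == 1
        assert (visits["duration_min"] == 2.0).all()

    def test_cell_change_splits(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T10:02:00Z", LAT_A, LON_A, 10),
            ("c1", "2020-03-01T10:04:00Z", LAT_B, LON_B, 10),
            ("c1", "2020-03-01T10:06:00Z", LAT_B, LON_B, 10),
        ])
        visits, _, _ = tj.segment_visits(fixes, 7)
        assert len(visits) == 2
        assert set(visits["code"]) == {CODE_A, gc.encode_geohash(gc.GeoPoint(LAT_B, LON_B), 7)}

    def _random_fixes(self, seed, n=300):
        rng = np.random.default_rng(seed)
        t0 = pd.Timestamp("2020-03-01T08:00:00Z")
        rows = []
        t = t0
        for child in ("a", "b"):
            t = t0
            lat, lon = 40.64, 22.94
            for _ in range(n):
                t = t + pd.Timedelta(seconds=int(rng.integers(20, 600)))
                if rng.uniform() < 0.2:
                    lat += rng.uniform(-0.01, 0.01)
                    lon += rng.uniform(-0.01, 0.01)
                rows.append((child, t.isoformat(), lat, lon, int(rng.integers(0, 50))))
        return make_fixes(rows)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariants_on_random_streams(self, seed):
        fixes = self._random_fixes(seed)
        visits, fvid, stats = tj.segment_visits(fixes, 7)
        assert stats["candidates"] == stats["retained"] + stats["dropped_short"]
        # visits of one child never overlap in time
        for _, g in visits.groupby("child_id"):
            g = g.sort_values("t_entry")
            assert (g["t_entry"].to_numpy()[1:] >= g["t_exit"].to_numpy()[:-1]).all()
        # total visit time bounded by total recorded span
        days = tj.summarize_days(fixes, max_gap_min=1e9)
        span = days.groupby("child_id")["recorded_min"].sum()
        dur = visits.groupby("child_id")["duration_min"].sum()
        for child in dur.index:
            assert dur[child] <= span[child] + 1e-9

    @pytest.mark.parametrize("seed", [0, 1])
    def test_min_duration_monotonicity(self, seed):
        fixes = self._random_fixes(seed)
        counts = [len(tj.segment_visits(fixes, 7, min_duration_min=m)[0]) for m in (0, 1, 5, 10, 30)]
        assert counts == sorted(counts, reverse=True)

    def test_precision7_visits_nest_in_precision6_spans(self):
        fixes = self._random_fixes(5)
        v7, _, _ = tj.segment_visits(fixes, 7)
        v6, _, _ = tj.segment_visits(fixes, 6)
        for _, row in v7.iterrows():
            parents = v6[(v6["child_id"] == row["child_id"])
                         & (v6["code"] == row["code"][:6])
                         & (v6["t_entry"] <= row["t_entry"])
                         & (v6["t_exit"] >= row["t_exit"])]
            # the parent may have been dropped by the duration filter, but if the
            # 7-digit visit lasted >= 1 min its 6-digit envelope did too
            assert len(parents) >= 1


class TestPoiContacts:
    def _run(self, fixes, pois, radius=50.0, dwell=2.0):
        visits, fvid, _ = tj.segment_visits(fixes, 7)
        f = tj._sorted_fixes(fixes)
        return tj.attach_poi_contacts(f, fvid, visits, pois, CategoryGroupMap(), radius, dwell)

    def test_no_poi_in_radius(self):
        fixes = make_fixes([("c1", f"2020-03-01T10:0{i}:00Z", LAT_A, LON_A, 0) for i in range(6)])
        pois = pd.DataFrame({"id": ["p1"], "category": ["fast_food"], "lat": [LAT_B], "lon": [LON_B]})
        out = self._run(fixes, pois)
        assert (out["contacts_fast_food_takeaway"] == 0).all()

    def test_stationary_contact(self):
        # POI ~11 m east of the child, 5-min stay, dwell threshold 2 min
        fixes = make_fixes([("c1", f"2020-03-01T10:0{i}:00Z", LAT_A, LON_A, 0) for i in range(6)])
        pois = pd.DataFrame({"id": ["p1"], "category": ["fast_food"], "lat": [LAT_A], "lon": [LON_A + 0.00013]})
        out = self._run(fixes, pois)
        assert out.iloc[0]["contacts_fast_food_takeaway"] == 1

    def test_two_pois_same_family(self):
        fixes = make_fixes([("c1", f"2020-03-01T10:0{i}:00Z", LAT_A, LON_A, 0) for i in range(6)])
        pois = pd.DataFrame({
            "id": ["p1", "p2"],
            "category": ["fast_food", "takeaway"],
            "lat": [LAT_A, LAT_A],
            "lon": [LON_A + 0.00013, LON_A - 0.00013],
        })
        out = self._run(fixes, pois)
        assert out.iloc[0]["contacts_fast_food_takeaway"] == 2

    def test_short_brush_past_no_contact(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T10:01:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T10:02:00Z", LAT_A, LON_A + 0.00300, 0),
        ])
        pois = pd.DataFrame({"id": ["p1"], "category": ["park"], "lat": [LAT_A], "lon": [LON_A]})
        out = self._run(fixes, pois, dwell=2.0)
        assert (out["contacts_park"] == 0).all()


class TestSummarizeDays:
    def test_forty_five_minute_day(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T10:45:00Z", LAT_A, LON_A, 100),
        ])
        days = tj.summarize_days(fixes, max_gap_min=60)
        assert len(days) == 1
        assert days.iloc[0]["recorded_min"] == 45.0 and days.iloc[0]["steps"] == 100

    def test_two_days(self):
        rows = [("c1", f"2020-03-01T10:{m:02d}:00Z", LAT_A, LON_A, 1) for m in range(0, 60, 2)]
        rows += [("c1", "2020-03-01T11:00:00Z", LAT_A, LON_A, 1),
                 ("c1", "2020-03-01T11:30:00Z", LAT_A, LON_A, 1)]  # 90 min recorded (caps off)
        rows += [("c2", "2020-03-02T09:00:00Z", LAT_A, LON_A, 0),
                 ("c2", "2020-03-02T09:30:00Z", LAT_A, LON_A, 5)]
        days = tj.summarize_days(make_fixes(rows), max_gap_min=60)
        assert len(days) == 2
        assert days[days["child_id"] == "c1"].iloc[0]["recorded_min"] == 90.0
        assert days[days["child_id"] == "c2"].iloc[0]["recorded_min"] == 30.0

    def test_gap_cap_applies(self):
        fixes = make_fixes([
            ("c1", "2020-03-01T10:00:00Z", LAT_A, LON_A, 0),
            ("c1", "2020-03-01T11:00:00Z", LAT_A, LON_A, 0),
        ])
        days = tj.summarize_days(fixes, max_gap_min=5)
        assert days.iloc[0]["recorded_min"] == 5.0

    def test_empty(self):
        assert len(tj.summarize_days(make_fixes([]))) == 0


class TestAssignResidence:
    def test_all_night_in_one_cell(self):
        fixes = make_fixes([("c1", f"2020-03-01T0{h}:00:00Z", LAT_A, LON_A, 0) for h in range(1, 6)])
        res = tj.assign_residence(fixes, 7, max_gap_min=120)
        assert list(res["code"]) == [CODE_A]

    def test_majority_night_cell_wins(self):
        rows = [("c1", f"2020-03-01T00:{m:02d}:00Z", LAT_A, LON_A, 0) for m in range(0, 60, 5)]
        rows += [("c1", f"2020-03-01T05:{m:02d}:00Z", LAT_B, LON_B, 0) for m in range(0, 15, 5)]
        res = tj.assign_residence(make_fixes(rows), 7)
        assert res.iloc[0]["code"] == CODE_A

    def test_tie_breaks_lexicographically(self):
        # cell A: 7 intra-cell intervals of 5 min = 35 min; cell B: the capped
        # 5-min transition interval plus 6 intra-cell intervals = 35 min. Tie.
        rows = [("c1", f"2020-03-01T01:{m:02d}:00Z", LAT_A, LON_A, 0) for m in range(0, 40, 5)]
        rows += [("c1", f"2020-03-01T03:{m:02d}:00Z", LAT_B, LON_B, 0) for m in range(0, 35, 5)]
        res = tj.assign_residence(make_fixes(rows), 7)
        code_b = gc.encode_geohash(gc.GeoPoint(LAT_B, LON_B), 7)
        assert res.iloc[0]["code"] == min(CODE_A, code_b)

    def test_no_night_fixes_excluded(self):
        fixes = make_fixes([("c1", f"2020-03-01T1{h}:00:00Z", LAT_A, LON_A, 0) for h in range(5)])
        assert len(tj.assign_residence(fixes, 7)) == 0
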