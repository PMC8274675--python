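import numpy as np
import pandas as pd
import pytest

from geobehave import synthetic
from geobehave.config import PipelineConfig


def make_fixes(rows):
    """rows: (child_id, iso_timestamp, lat, lon, steps)."""
    df = pd.DataFrame(rows, columns=["child_id", "t", "lat", "lon", "steps"])
    df["t"] = pd.to_datetime(df["t"], utc=True)
    df["steps"] = df["steps"].astype(np.int64)
    return df.sort_values(["child_id", "t"], kind="mergesort").reset_index(drop=True)


def make_visits(rows, contact_tags=()):
    """rows: (child_id, code, duration_min, steps, {tag: contacts})."""
    from geobehave.config import ALL_TAGS

    columns = ["visit_id", "child_id", "code", "t_entry", "t_exit", "duration_min", "steps"] + \
        [f"contacts_{t}" for t in ALL_TAGS]
    if not rows:
        return pd.DataFrame(columns=columns)
    recs = []
    t0 = pd.Timestamp("2020-03-01T10:00:00Z")
    for i, (child, code, dur, steps, *rest) in enumerate(rows):
        contacts = rest[0] if rest else {}
        rec = {
            "visit_id": i,
            "child_id": child,
            "code": code,
            "t_entry": t0,
            "t_exit": t0 + pd.Timedelta(minutes=dur),
            "duration_min": float(dur),
            "steps": int(steps),
        }
        for tag in ALL_TAGS:
            rec[f"contacts_{tag}"] = int(contacts.get(tag, 0))
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_sim():
    """A small coupled city + cohort shared by pipeline-level tests."""
    cfg = synthetic.SimConfig(seed=7, n_children=30, n_days=3)
    city = synthetic.generate_city(cfg)
    fixes = synthetic.generate_cohort(cfg, city)
    return cfg, city, fixes


@pytest.fixture()
def pcfg():
    return PipelineConfig()
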