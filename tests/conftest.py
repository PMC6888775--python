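import logging

import numpy as np
import pandas as pd
import pytest

from fucusstat.habitat import SUBSTRATE_CLASSES
from fucusstat.synthetic import SimulationConfig

logging.getLogger("fucusstat").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Cheap generator config for structural tests."""
    return SimulationConfig(n_zones=12, n_points_per_zone=30, n_transects=30)


def make_points(
    rows: list[dict], default_substrate: str = "bedrock"
) -> pd.DataFrame:
    """Survey-point table builder: fills the 11 substrate columns.

    Each row dict may give explicit class covers; the remainder is dumped on
    ``default_substrate`` (or 'sand' when the row should be soft).
    """
    records = []
    for i, row in enumerate(rows):
        rec = {
            "point_id": row.get("point_id", i),
            "zone_id": row.get("zone_id", 0),
            "x": row.get("x", 0.0),
            "y": row.get("y", 0.0),
            "depth_m": row.get("depth_m", 1.0),
            "method": row.get("method", "video"),
            "fucus_cover_pct": row.get("fucus_cover_pct", 0.0),
        }
        covers = {c: float(row.get(c, 0.0)) for c in SUBSTRATE_CLASSES}
        total = sum(covers.values())
        if total < 100:
            filler = row.get("filler", default_substrate)
            covers[filler] += 100 - total
        rec.update(covers)
        if "potential" in row:
            rec["potential"] = row["potential"]
        records.append(rec)
    return pd.DataFrame(records)


def make_transect(
    covers, depths=None, distances=None, hard=None, transect_id=0
) -> pd.DataFrame:
    """Transect table builder from parallel lists."""
    n = len(covers)
    depths = list(depths) if depths is not None else list(range(1, n + 1))
    distances = (
        list(distances) if distances is not None else [10.0 * i for i in range(n)]
    )
    hard = list(hard) if hard is not None else [80.0] * n
    rows = []
    for i in range(n):
        rec = {
            "transect_id": transect_id,
            "distance_m": distances[i],
            "depth_m": depths[i],
            "fucus_cover_pct": covers[i],
        }
        for c in SUBSTRATE_CLASSES:
            rec[c] = 0.0
        rec["bedrock"] = hard[i]
        rec["sand"] = 100.0 - hard[i]
        rows.append(rec)
    return pd.DataFrame(rows)
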