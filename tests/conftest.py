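from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """Compact raw-capable cohort for fast end-to-end exercises."""
    from skatemove.synthetic import SimConfig

    return SimConfig(
        n_individuals=8,
        study_start=date(2019, 5, 5),
        study_end=date(2020, 11, 1),
        raw_days_per_individual=12,
        seed=42,
    )


def detections_frame(times_hours, transmitter="A"):
    """Detection table from offsets in hours (single receiver)."""
    t0 = pd.Timestamp("2020-06-01", tz="UTC")
    rows = []
    for item in times_hours:
        if isinstance(item, tuple):
            tid, h = item
        else:
            tid, h = transmitter, item
        rows.append({
            "timestamp": t0 + pd.Timedelta(hours=float(h)),
            "receiver_id": "R01",
            "transmitter_id": tid,
            "depth_m": np.nan,
        })
    return pd.DataFrame(rows)
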