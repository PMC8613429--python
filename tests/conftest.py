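"""Shared fixtures: tiny deterministic cohorts and hand-built schedules."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from typetrail.config import GeneratorConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

UTC_DAY0 = dt.datetime(2021, 1, 4, tzinfo=dt.timezone.utc)


def ts_ms(day: int, hour: float) -> int:
    """Epoch ms of study day (1-based) at fractional hour, UTC."""
    t = UTC_DAY0 + dt.timedelta(days=day - 1, hours=hour)
    return int(t.timestamp() * 1000)


def dtmt_frame(rows: list[tuple[str, int, str]], completion: float = 20.0) -> pd.DataFrame:
    """Test records from (subject, timestamp_ms, slot) triples."""
    return pd.DataFrame(
        {
            "subject_id": [r[0] for r in rows],
            "timestamp_ms": np.array([r[1] for r in rows], dtype=np.int64),
            "completion_time_s": completion,
            "wrong_moves": 1,
            "variant_id": 1,
            "slot": [r[2] for r in rows],
        }
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_control=3, n_bipolar=4, missingness=0.2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from typetrail.synthetic import generate_cohort

    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def six_day_schedule() -> pd.DataFrame:
    """Six study days covering every windowing regime: two-test days,
    morning-only and evening-only days, and a three-day gap."""
    rows = [
        ("A", ts_ms(1, 9.0), "morning"),
        ("A", ts_ms(1, 21.0), "evening"),
        ("A", ts_ms(2, 8.5), "morning"),  # evening missed
        ("A", ts_ms(5, 20.5), "evening"),  # after a long gap, morning missed
        ("A", ts_ms(6, 9.25), "morning"),
        ("A", ts_ms(6, 21.25), "evening"),
    ]
    return dtmt_frame(rows)
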