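import dataclasses

import numpy as np
import pandas as pd
import pytest

from circaclock import (
    LightSchedule,
    MonitorFile,
    paper_presets,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tau_schedule() -> LightSchedule:
    """4 days LD 16:8 entrainment followed by 10 days DD."""
    return LightSchedule.ld_dd(16.0, 4, 10)


@pytest.fixture(scope="session")
def ld16_schedule() -> LightSchedule:
    return LightSchedule.ld_only(16.0, 10)


def random_monitor(rng: np.random.Generator, n_rows: int = 120) -> MonitorFile:
    """A valid random MonitorFile on a 1-min grid."""
    t0 = pd.Timestamp("2019-03-04 08:00:00")
    return MonitorFile(
        monitor_id="MonitorX",
        timestamps=pd.date_range(t0, periods=n_rows, freq="min"),
        status=np.ones(n_rows, dtype=np.int64),
        light_sensor=rng.integers(0, 2, n_rows),
        counts=rng.poisson(2.0, size=(n_rows, 32)),
    )


@pytest.fixture(scope="session")
def small_south_cohort():
    """Six simulated southern isogenic individuals (LD then DD), cached."""
    spec = dataclasses.replace(paper_presets()["south_isogenic"], n=6, master_seed=42)
    return simulate_cohort(spec)
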