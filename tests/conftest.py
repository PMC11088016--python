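import datetime as dt

import numpy as np
import pytest

from stcluster import Event, EventSet, SimConfig, simulate


@pytest.fixture
def small_events() -> EventSet:
    """Ten hand-built events with a mix of covariates and missing cells."""
    base = dt.date(2018, 3, 1)
    events = []
    for i in range(10):
        events.append(
            Event(
                id=f"e{i}",
                lat=35.0 + 0.01 * i,
                lon=127.0 + 0.02 * i,
                date=base + dt.timedelta(days=3 * i),
                sex="male" if i % 2 == 0 else "female",
                school_type=("elementary", "middle", "high")[i % 3],
                economic_status="missing" if i == 4 else ("upper", "middle", "lower")[i % 3],
                psychiatric_history="yes" if i < 3 else "no",
                age=float(14 + i % 4),
                sdq_total=float(i) if i % 2 == 0 else None,
            )
        )
    return EventSet(events=events)


@pytest.fixture(scope="session")
def default_sim():
    """One simulated scenario under the frozen default conditions."""
    events, truth = simulate(SimConfig(seed=7))
    return events, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
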