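import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cgmkit import GlucoseTrace

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

START = pd.Timestamp("2024-03-01 00:00:00")


def build_trace(values, interval=5.0, start=START, subject_id="T001", times_min=None):
    """Regular-cadence trace from glucose values, or explicit minute offsets."""
    values = np.asarray(values, dtype=float)
    if times_min is None:
        times_min = np.arange(len(values)) * interval
    times = pd.DatetimeIndex(start + pd.to_timedelta(times_min, unit="m"))
    return GlucoseTrace(subject_id, times, values)


@pytest.fixture
def make_trace():
    return build_trace


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
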