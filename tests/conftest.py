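import numpy as np
import pandas as pd
import pytest

from lge_gv.cgm_io import GlucoseTrace

START = pd.Timestamp("2021-03-01 00:00:00")


def make_trace(values, start=START, cadence_minutes=15, participant_id="P1",
               week=0, timestamps=None):
    """Build a GlucoseTrace from raw values on a regular grid (or explicit times)."""
    values = np.asarray(values, dtype=float)
    if timestamps is None:
        timestamps = start + pd.to_timedelta(
            np.arange(len(values)) * cadence_minutes, unit="m")
    return GlucoseTrace(participant_id, week, pd.DatetimeIndex(timestamps),
                        values, cadence_minutes=float(cadence_minutes))


def random_walk_trace(rng, n_days=2, cadence_minutes=15, drop_fraction=0.1,
                      participant_id="P1"):
    """Random-walk CGM-like trace with random deletions (gaps), values in 45-350."""
    n = int(n_days * 1440 / cadence_minutes)
    steps = rng.normal(0, 6, size=n)
    vals = np.clip(100 + np.cumsum(steps), 45, 350)
    keep = rng.random(n) > drop_fraction
    keep[0] = keep[-1] = True
    ts = START + pd.to_timedelta(np.arange(n)[keep] * cadence_minutes, unit="m")
    return make_trace(vals[keep], timestamps=ts, cadence_minutes=cadence_minutes,
                      participant_id=participant_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240410)


@pytest.fixture
def constant_trace():
    return make_trace([100.0] * 200)
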