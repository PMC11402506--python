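import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import vultrack as vt

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_traj(times, lon, lat, individual_id="bird", nest=(0.0, 0.0),
              tagging_date=None, nucleus="TestNucleus", sex="F", **channels):
    """Build a Trajectory from plain arrays; optional hdop/vdop/battery_v/
    activity channels default to missing."""
    times = pd.DatetimeIndex(times)
    n = len(times)
    data = {"timestamp": times, "lon": np.asarray(lon, dtype=float),
            "lat": np.asarray(lat, dtype=float)}
    for col in ("hdop", "vdop", "battery_v", "activity"):
        data[col] = np.asarray(channels.get(col, np.full(n, np.nan)), dtype=float)
    dep = vt.Deployment(individual_id=individual_id, sex=sex, nucleus=nucleus,
                        nest_lon=nest[0], nest_lat=nest[1],
                        tagging_date=pd.Timestamp(tagging_date) if tagging_date
                        else times[0].normalize() if n else None)
    return vt.Trajectory(dep, pd.DataFrame(data))


def hourly_times(start, n, step_hours=0.5):
    return pd.date_range(start, periods=n, freq=pd.Timedelta(hours=step_hours))


@pytest.fixture(scope="session")
def small_cohort():
    """An 11-bird simulated cohort with ground truth (2 residents)."""
    cfg = vt.SimulationConfig(
        seed=11,
        nucleus_counts={"Arribes": 6, "Galicia": 3, "Segovia": 2},
        n_non_migrants=2)
    trajs, truths = vt.simulate_cohort(cfg)
    return cfg, trajs, truths


@pytest.fixture(scope="session")
def small_cohort_clean(small_cohort):
    cfg, trajs, truths = small_cohort
    clean = [vt.resample(vt.qc_filter(t), "30min") for t in trajs]
    segs = [vt.segment(t) for t in clean]
    return cfg, clean, segs, truths
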