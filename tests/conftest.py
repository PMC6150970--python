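import numpy as np
import pandas as pd
import pytest

from travelmode.pipeline import cohort_feature_rows
from travelmode.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, one 60-min day each: enough for 5-fold CV with all
    five modes present, small enough to simulate once per session."""
    cfg = SimConfig(seed=7, n_participants=6, n_days=1, day_minutes=60)
    network, participants, truth = simulate_cohort(cfg)
    return cfg, network, participants, truth


@pytest.fixture(scope="session")
def small_cohort_rows(small_cohort):
    _, network, participants, truth = small_cohort
    return cohort_feature_rows(participants, network, 4.0, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_participant(small_cohort):
    _, network, participants, truth = small_cohort
    pid, (accel, gps) = next(iter(participants.items()))
    return network, pid, accel, gps, truth


def random_epoch_table(rng, n, gap_at=(), t0="2024-03-04 08:00:00"):
    """A minimal epoch-feature table with random values, optionally with
    missing epochs (gaps) to break contiguity."""
    from travelmode.epoch_features import ACCEL_FEATURES
    starts = pd.date_range(t0, periods=n + len(gap_at), freq="10s", tz="UTC")
    keep = [i for i in range(len(starts)) if i not in set(gap_at)][:n]
    df = pd.DataFrame({"participant_id": "P001",
                       "epoch_start": starts[keep]})
    for c in ACCEL_FEATURES:
        df[c] = rng.normal(size=n)
    df["speed_kmh"] = rng.uniform(0, 50, size=n)
    df["sum_snr"] = rng.uniform(0, 400, size=n)
    df["rail_dist_m"] = rng.uniform(0, 2000, size=n)
    df["lat"] = 51.5 + rng.normal(0, 0.01, size=n)
    df["lon"] = -0.1 + rng.normal(0, 0.01, size=n)
    df["has_gps"] = rng.random(n) > 0.2
    df.loc[~df["has_gps"], ["speed_kmh", "sum_snr", "rail_dist_m",
                            "lat", "lon"]] = np.nan
    df["nonwear"] = False
    return df
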