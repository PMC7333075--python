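import numpy as np
import pandas as pd
import pytest

from zonescreen.replay_model import FRAME_COLUMNS, DriveRecording
from zonescreen.synthetic_sim import (DriverProfile, SimParams,
                                      generate_cohort,
                                      generate_environment_bank,
                                      simulate_drive)

#: Reduced-scale bank parameters used throughout the unit tests.
SMALL_BANK = dict(n_env=2, total_zones=12, route_length=650.0, zone_scale=0.4)


@pytest.fixture(scope="session")
def small_bank():
    return generate_environment_bank(seed=42, **SMALL_BANK)


@pytest.fixture(scope="session")
def small_cohort(small_bank):
    """60 simulated drivers on the reduced bank (recordings + records)."""
    return generate_cohort(60, small_bank, params=SimParams(), seed=42)


@pytest.fixture(scope="session")
def one_drive(small_bank):
    return simulate_drive(small_bank[0], DriverProfile(theta=0.4, seed=77),
                          SimParams())


def make_recording(speeds, dt=0.1, drive_id="t0", limit=15.0, **overrides):
    """Minimal hand-built recording with the given speed trace."""
    n = len(speeds)
    data = {
        "t": np.arange(n) * dt,
        "x": np.concatenate([[0.0],
                             np.cumsum(np.asarray(speeds, dtype=float)[:-1] * dt)]),
        "y": np.zeros(n),
        "heading": np.zeros(n),
        "speed": np.asarray(speeds, dtype=float),
        "brake": np.zeros(n),
        "throttle": np.full(n, 0.3),
        "steering": np.zeros(n),
        "lane_offset": np.zeros(n),
        "turn_signal": ["none"] * n,
        "scan_left": np.zeros(n, dtype=bool),
        "scan_right": np.zeros(n, dtype=bool),
        "posted_limit": np.full(n, float(limit)),
    }
    data.update(overrides)
    frames = pd.DataFrame(data, columns=list(FRAME_COLUMNS))
    return DriveRecording(drive_id=drive_id, environment_id=1, frames=frames)
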