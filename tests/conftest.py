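import numpy as np
import pandas as pd
import pytest

import splitmaze as sm
from splitmaze.simulate import ErrorModel, SessionConfig


@pytest.fixture(scope="session")
def layout():
    return sm.build_maze_layout()


@pytest.fixture(scope="session")
def clean_session(layout):
    """Error-free default session (4 blocks x 11+ rewarded trials)."""
    cfg = SessionConfig(seed=101, error_model=ErrorModel(p_post=0.0))
    traj, trials = sm.simulate_session(layout, cfg)
    return traj, trials


@pytest.fixture(scope="session")
def route2_cell(layout, clean_session):
    """Start-box cell firing four-fold stronger on route 2, with its
    per-trial start-box statistics."""
    traj, trials = clean_session
    spec = sm.CellSpec(field_centers=((0.0, 0.0),), peak_rate=4.0, route_gains=(1, 4, 1, 1))
    st = sm.simulate_place_cell(spec, traj, seed=202)
    stats = sm.sector_trial_stats(st, traj, trials, "start_box", layout)
    return spec, st, stats


def square_traj(side=20.0, duration=10.0, rate=50.0, origin=(0.0, 0.0), seed=0):
    """Synthetic trajectory wandering uniformly in a square (test helper)."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    t = np.arange(n) / rate
    xy = rng.uniform(0, side, (n, 2)) + np.asarray(origin)
    return pd.DataFrame(
        {"t": t, "x": xy[:, 0], "y": xy[:, 1], "trial_id": 0, "route_id": 1, "phase": "run"}
    )
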