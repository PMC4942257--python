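"""Kernel rate maps, spatial information and field counting."""

import numpy as np
import pandas as pd
import pytest

import splitmaze as sm
from splitmaze.ratemaps import RateMap, SmoothingParams, compute_occupancy
from splitmaze.simulate import CellSpec

from conftest import square_traj
from oracles import brute_force_rate_map


def _uniform_map(rates, occ=None):
    """RateMap over a small fully-visited grid (test helper)."""
    rates = np.asarray(rates, float)
    ny, nx = rates.shape
    occ = np.ones_like(rates) if occ is None else np.asarray(occ, float)
    return RateMap(
        x_centres=np.arange(nx, dtype=float),
        y_centres=np.arange(ny, dtype=float),
        rate=rates,
        occupancy=occ,
        raw_occupancy=occ,
        visited=np.ones_like(rates, dtype=bool),
        params=SmoothingParams(),
    )


@pytest.mark.parametrize("u,expected", [(0.0, 1.0), (1.0, np.exp(-0.5)), (2.0, np.exp(-2.0))])
def test_gaussian_kernel_values(u, expected):
    assert sm.gaussian_kernel(u) == pytest.approx(expected)
    assert sm.gaussian_kernel(-u) == sm.gaussian_kernel(u)


def test_stationary_rate_equals_count_over_time():
    # rat parked at one point for T seconds with n spikes: kernel weights
    # cancel and the map reads n/T everywhere visited
    n, T, rate_hz = 12, 30.0, 50.0
    t = np.arange(int(T * rate_hz)) / rate_hz
    traj = pd.DataFrame({"t": t, "x": 5.0, "y": 5.0, "trial_id": 0, "route_id": 1, "phase": "hold"})
    spikes = np.linspace(1.0, 25.0, n)
    rm = sm.compute_rate_map(spikes, traj)
    assert np.allclose(rm.rate[rm.visited], n / T)


def test_no_spikes_gives_zero_map():
    rm = sm.compute_rate_map([], square_traj(seed=1))
    assert np.all(rm.rate[rm.visited] == 0)
    assert np.isnan(rm.rate[~rm.visited]).all()


def test_rate_map_matches_double_loop_oracle():
    traj = square_traj(side=25.0, duration=4.0, seed=3)
    spikes = np.sort(np.random.default_rng(4).uniform(0.2, 3.8, 20))
    params = SmoothingParams(h=2.5, bin_size=2.5, visit_radius=30.0)
    rm = sm.compute_rate_map(spikes, traj, params)
    gx, gy = np.meshgrid(rm.x_centres, rm.y_centres)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    t = traj["t"].to_numpy()
    dt = np.concatenate([np.diff(t), [t[1] - t[0]]])
    spos = np.column_stack(
        [np.interp(spikes, t, traj["x"]), np.interp(spikes, t, traj["y"])]
    )
    oracle = brute_force_rate_map(spos, traj[["x", "y"]].to_numpy(), dt, centres, params.h)
    assert np.nanmax(np.abs(rm.rate.ravel() - oracle)) < 1e-10


def _serpentine_traj(side=20.0, duration=600.0, rate=10.0):
    """Continuous raster path covering a square uniformly."""
    n = int(duration * rate)
    t = np.arange(n) / rate
    speed = 8.0  # cm/s along the sweep
    s = speed * t
    row_len = side
    row = (s // row_len).astype(int)
    frac = s % row_len
    x = np.where(row % 2 == 0, frac, side - frac)
    y = (row * 2.9) % side
    return pd.DataFrame({"t": t, "x": x, "y": y, "trial_id": 0, "route_id": 1, "phase": "run"})


def test_homogeneous_poisson_recovers_rate():
    r_hz = 3.0
    traj = _serpentine_traj()
    rng = np.random.default_rng(7)
    n = rng.poisson(r_hz * 600.0)
    spikes = np.sort(rng.uniform(0, 600.0, n))
    rm = sm.compute_rate_map(spikes, traj)
    mean_rate = np.mean(rm.rate[rm.visited])
    assert abs(mean_rate - r_hz) / r_hz < 0.10


def test_time_reversed_session_gives_identical_map():
    traj = square_traj(side=20.0, duration=5.0, seed=8)
    spikes = np.sort(np.random.default_rng(9).uniform(0.1, 4.9, 30))
    T = traj["t"].iloc[-1]
    rev = traj.iloc[::-1].copy()
    rev["t"] = T - rev["t"].to_numpy()
    rev = rev.reset_index(drop=True)
    rm1 = sm.compute_rate_map(spikes, traj)
    rm2 = sm.compute_rate_map(np.sort(T - spikes), rev)
    np.testing.assert_allclose(rm1.rate, rm2.rate, rtol=1e-9, equal_nan=True)


def test_visit_mask_monotone_in_radius():
    class _FixedBox:
        def bounding_box(self):
            return (0.0, 0.0, 30.0, 30.0)

    traj = square_traj(side=30.0, duration=3.0, seed=10)
    box = _FixedBox()
    small = compute_occupancy(traj, SmoothingParams(visit_radius=3.0), box)
    large = compute_occupancy(traj, SmoothingParams(visit_radius=8.0), box)
    assert np.all(large.visited[small.visited])


def test_spatial_information_closed_forms():
    # uniform rate over uniform occupancy carries no information
    assert sm.spatial_information(_uniform_map(np.full((2, 2), 3.0))) == pytest.approx(0.0)
    # four equally occupied bins with rates (4R, 0, 0, 0): 2 bits/spike
    assert sm.spatial_information(_uniform_map([[8.0, 0.0], [0.0, 0.0]])) == pytest.approx(2.0)
    # all-zero map: zero by convention
    assert sm.spatial_information(_uniform_map(np.zeros((2, 2)))) == 0.0


def test_spatial_information_scale_invariant_and_nonnegative():
    rng = np.random.default_rng(11)
    for _ in range(10):
        rates = rng.uniform(0, 5, (4, 4))
        occ = rng.uniform(0.5, 2.0, (4, 4))
        m1 = _uniform_map(rates, occ)
        m2 = _uniform_map(rates * 7.5, occ)
        i1, i2 = sm.spatial_information(m1), sm.spatial_information(m2)
        assert i1 >= 0
        assert i1 == pytest.approx(i2)


def test_count_place_fields():
    z = np.zeros((12, 12))
    gx, gy = np.meshgrid(np.arange(12), np.arange(12))
    one_bump = 5.0 * np.exp(-((gx - 4) ** 2 + (gy - 4) ** 2) / 6.0)
    n, _ = sm.count_place_fields(_uniform_map(one_bump))
    assert n == 1
    two_bumps = one_bump + 5.0 * np.exp(-((gx - 9) ** 2 + (gy - 9) ** 2) / 2.0)
    n, labels = sm.count_place_fields(_uniform_map(two_bumps))
    assert n == 2
    assert labels.max() == 2
    n, _ = sm.count_place_fields(_uniform_map(z))
    assert n == 0


def test_sector_activity_profile_start_box_population(layout, clean_session):
    traj, _ = clean_session
    rng = np.random.default_rng(12)
    cells = {}
    for i in range(12):
        spec = CellSpec(field_centers=(tuple(rng.uniform(-4, 4, 2)),), field_width=4.0, peak_rate=6.0, baseline_rate=0.0)
        cells[f"c{i}"] = sm.simulate_place_cell(spec, traj, seed=int(rng.integers(2**31)))
    profile, (r, p, df) = sm.sector_activity_profile(cells, traj, layout)
    assert len(profile) == 14
    start_row = profile.set_index("sector").loc["start_box"]
    assert start_row["n_active"] == 12
    assert profile.set_index("sector").loc["right_goal_box", "n_active"] == 0
    assert r < -0.5
    assert df == 12


@pytest.mark.filterwarnings("ignore::scipy.stats.ConstantInputWarning")
def test_tonic_cell_active_in_all_sectors(layout, clean_session):
    traj, _ = clean_session
    spec = CellSpec(field_centers=((0.0, 0.0),), peak_rate=0.0, baseline_rate=3.0)
    st = sm.simulate_place_cell(spec, traj, seed=3)
    profile, _ = sm.sector_activity_profile({"c": st}, traj, layout)
    assert (profile["n_active"] == 1).all()
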