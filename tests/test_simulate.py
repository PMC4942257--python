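"""Behavioral protocol and spike-generator contracts of the simulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import splitmaze as sm
from splitmaze.simulate import CellSpec, ErrorModel, SessionConfig
from splitmaze.simulate import intensity_at


def test_seeded_determinism(layout):
    cfg = SessionConfig(seed=7, n_blocks=2)
    t1, tr1 = sm.simulate_session(layout, cfg)
    t2, tr2 = sm.simulate_session(layout, cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(tr1, tr2)
    spec = CellSpec(field_centers=((0.0, 0.0),))
    s1 = sm.simulate_place_cell(spec, t1, seed=3)
    s2 = sm.simulate_place_cell(spec, t1, seed=3)
    np.testing.assert_array_equal(s1, s2)


def test_error_free_blocks_have_full_rewarded_runs(layout):
    cfg = SessionConfig(seed=11, error_model=ErrorModel(p_post=0.0))
    _, trials = sm.simulate_session(layout, cfg)
    assert trials["block"].nunique() == 4
    for _, g in trials.groupby("block"):
        post = g[~g["is_search"]]
        # with zero post-identification error probability: at least 11
        # trials after the first correct, all of them correct
        assert len(post) >= cfg.trials_per_block
        assert post["correct"].all()
        # search phase ends with exactly one correct trial
        search = g[g["is_search"]]
        assert search["correct"].sum() == 1
        assert search["correct"].iloc[-1]


def test_search_errors_visit_unrewarded_goals_first(layout):
    # with enough blocks some searches must start at a wrong box, and every
    # search error precedes the block's first correct trial
    cfg = SessionConfig(seed=13, n_blocks=4, error_model=ErrorModel(p_post=0.0))
    _, trials = sm.simulate_session(layout, cfg)
    search_errors = trials[trials["is_search"] & ~trials["correct"]]
    assert len(search_errors) > 0
    for _, g in trials.groupby("block"):
        first_correct = g.loc[g["correct"]].iloc[0]["trial_id"]
        assert (g.loc[~g["correct"] & g["is_search"], "trial_id"] < first_correct).all()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SessionConfig(route_schedule=())
    with pytest.raises(ValueError):
        SessionConfig(route_schedule=(1, 5))
    with pytest.raises(ValueError):
        SessionConfig(trials_per_block=4, min_correct_per_block=6)
    with pytest.raises(ValueError):
        CellSpec(route_gains=(1, 1, 1))
    with pytest.raises(ValueError):
        CellSpec(peak_rate=-1)


def test_route_gain_raises_start_box_rate(layout):
    # ~40 trials per route on routes 1 and 2 only
    cfg = SessionConfig(
        seed=21,
        n_blocks=8,
        trials_per_block=10,
        route_schedule=(1, 2) * 4,
        error_model=ErrorModel(p_post=0.0),
    )
    traj, trials = sm.simulate_session(layout, cfg)
    spec = CellSpec(field_centers=((0.0, 0.0),), peak_rate=4.0, route_gains=(1, 4, 1, 1))
    st = sm.simulate_place_cell(spec, traj, seed=5)
    stats = sm.sector_trial_stats(st, traj, trials, "start_box", layout)
    r1 = stats.loc[stats["route_id"] == 1, "firing_rate"]
    r2 = stats.loc[stats["route_id"] == 2, "firing_rate"]
    assert len(r1) >= 35 and len(r2) >= 35
    res = sps.mannwhitneyu(r2, r1, alternative="greater")
    assert res.pvalue < 0.01


def test_no_modulation_gives_equal_route_rates(layout, clean_session):
    traj, trials = clean_session
    spec = CellSpec(field_centers=((0.0, 0.0),), peak_rate=4.0)
    st = sm.simulate_place_cell(spec, traj, seed=9)
    stats = sm.sector_trial_stats(st, traj, trials, "start_box", layout)
    means = stats.groupby("route_id")["firing_rate"].mean()
    assert means.max() - means.min() < 0.35 * means.mean()


def test_spike_count_matches_intensity_integral(layout):
    cfg = SessionConfig(seed=31, n_blocks=1, trials_per_block=6)
    traj, _ = sm.simulate_session(layout, cfg)
    spec = CellSpec(field_centers=((0.0, 0.0),), peak_rate=6.0, route_gains=(1, 2, 1, 1))
    # oracle: integrate the intensity along the interpolated path (the same
    # position definition the thinning generator uses) on a fine time grid
    t = traj["t"].to_numpy()
    tf = np.linspace(t[0], t[-1], 10 * len(t))
    idx = np.clip(np.searchsorted(t, tf, side="right") - 1, 0, len(t) - 1)
    fine = pd.DataFrame(
        {
            "t": tf,
            "x": np.interp(tf, t, traj["x"]),
            "y": np.interp(tf, t, traj["y"]),
            "route_id": traj["route_id"].to_numpy()[idx],
        }
    )
    expected = np.trapezoid(intensity_at(spec, fine), tf)
    counts = [len(sm.simulate_place_cell(spec, traj, seed=s)) for s in range(200)]
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se + 1e-9


def test_empirical_rate_converges_to_programmed_intensity(layout):
    # ~600 s of dwell in the start box: empirical rate within 10 percent
    cfg = SessionConfig(seed=41, n_blocks=4, inter_trial_hold=(12.0, 15.0))
    traj, _ = sm.simulate_session(layout, cfg)
    hold = traj[traj["phase"] == "hold"]
    assert hold["t"].count() / cfg.position_rate > 600
    spec = CellSpec(field_centers=((0.0, 0.0),), field_width=30.0, peak_rate=4.0, baseline_rate=0.0)
    st = sm.simulate_place_cell(spec, traj, seed=2)
    t = traj["t"].to_numpy()
    idx = np.clip(np.searchsorted(t, st) - 1, 0, len(t) - 1)
    in_hold = np.isin(idx, np.flatnonzero((traj["phase"] == "hold").to_numpy()))
    dwell = len(hold) / cfg.position_rate
    programmed = intensity_at(spec, hold).mean()
    empirical = in_hold.sum() / dwell
    assert abs(empirical - programmed) / programmed < 0.10


def test_feature_cloud_contract():
    fc1 = sm.simulate_feature_cloud(100, 200, separation=8.0, dim=8, seed=4)
    fc2 = sm.simulate_feature_cloud(100, 200, separation=8.0, dim=8, seed=4)
    np.testing.assert_array_equal(fc1.cluster_points, fc2.cluster_points)
    np.testing.assert_array_equal(fc1.noise_points, fc2.noise_points)
    assert fc1.cluster_points.shape == (100, 8)
    with pytest.raises(ValueError):
        sm.simulate_feature_cloud(8, 10, 1.0, dim=8)  # n_c must exceed dim
    with pytest.raises(ValueError):
        sm.simulate_feature_cloud(20, 0, 1.0, dim=8)
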