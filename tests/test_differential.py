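"""Differential-firing tests, pattern classification and population tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from shapely.geometry import Polygon

import splitmaze as sm
from splitmaze.differential import DifferentialFiring, DifferentialFiringResults

from oracles import brute_force_ranked_ancova, exact_chisquare


def _stats_frame(rates, routes, rng=None, counts=None, times=None):
    """Assemble a TrialSectorStats frame with benign covariates."""
    rng = rng or np.random.default_rng(0)
    n = len(rates)
    times = np.ones(n) if times is None else np.asarray(times, float)
    counts = np.rint(np.asarray(rates) * times) if counts is None else counts
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "route_id": np.asarray(routes, int),
            "firing_rate": np.asarray(rates, float),
            "mean_x": rng.normal(0, 1, n),
            "mean_y": rng.normal(0, 1, n),
            "mean_speed": rng.normal(10, 1, n),
            "time_in_sector": times,
            "n_spikes": np.asarray(counts, int),
        }
    )


def _posthoc_table(sig_pairs, alpha=0.05):
    rows = []
    for a, b in ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)):
        p = alpha / 10 if {a, b} in [set(s) for s in sig_pairs] else 0.5
        rows.append(dict(route_a=a, route_b=b, estimate=1.0, p=p))
    return pd.DataFrame(rows)


def _result_with(posthoc):
    return DifferentialFiringResults(
        method="ranked_ancova", statistic=10.0, p_value=0.001, df=(3, 40),
        posthoc=posthoc, n_trials=pd.Series({r: 11 for r in (1, 2, 3, 4)}), alpha=0.05,
    )


# ---- per-trial sector statistics -------------------------------------


def test_sector_stats_arithmetic():
    # 2 s in a square sector with 6 spikes -> 3 Hz; 20 cm path in the
    # sector over 2 s -> 10 cm/s
    poly = Polygon([(0, 0), (10, 0), (10, 30), (0, 30)])
    n = 100
    t = np.arange(n) / 50.0
    x = np.full(n, 5.0)
    y = np.linspace(0.0, 19.8, n)  # 20 cm in 2 s, leaves the sector never
    traj = pd.DataFrame({"t": t, "x": x, "y": y, "trial_id": 0, "route_id": 2, "phase": "run"})
    trials = pd.DataFrame(
        [dict(trial_id=0, route_id=2, rewarded_route=2, correct=True, t_hold_start=0.0,
              t_start=0.0, t_goal=2.0, t_end=2.0, duration=2.0)]
    )
    spikes = np.linspace(0.1, 1.9, 6)
    out = sm.sector_trial_stats(spikes, traj, trials, poly)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["firing_rate"] == pytest.approx(3.0)
    assert row["mean_speed"] == pytest.approx(10.0, rel=0.02)
    assert row["mean_x"] == pytest.approx(5.0)
    # a trial that never enters the sector produces no row
    far = Polygon([(100, 100), (110, 100), (110, 110), (100, 110)])
    assert len(sm.sector_trial_stats(spikes, traj, trials, far)) == 0


def test_boundary_spike_follows_polygon_convention():
    poly = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
    t = np.arange(50) / 50.0
    traj = pd.DataFrame({"t": t, "x": 10.0, "y": 5.0, "trial_id": 0, "route_id": 1, "phase": "run"})
    trials = pd.DataFrame(
        [dict(trial_id=0, route_id=1, rewarded_route=1, correct=True, t_hold_start=0.0,
              t_start=0.0, t_goal=1.0, t_end=1.0, duration=1.0)]
    )
    # position samples sit exactly on the boundary: the inclusive convention
    # counts them, and a spike interpolated onto the boundary likewise
    out = sm.sector_trial_stats([0.5], traj, trials, poly)
    assert len(out) == 1 and out.iloc[0]["n_spikes"] == 1


def test_active_rule():
    stats = _stats_frame([0.2, 1.5, 0.3, 0.1], [1, 2, 3, 4], times=[10.0] * 4,
                         counts=[2, 15, 3, 1])
    assert sm.is_active_in_sector(stats)
    flat = _stats_frame([1.0] * 4, [1, 2, 3, 4], times=[10.0] * 4, counts=[10] * 4)
    assert not sm.is_active_in_sector(flat)  # strictly greater than 1 Hz
    assert not sm.is_active_in_sector(flat.iloc[:0])


# ---- ranked ANCOVA ----------------------------------------------------


def test_ranked_ancova_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n_per = int(rng.integers(5, 12))
        routes = np.repeat([1, 2, 3, 4], n_per)
        rates = rng.gamma(2.0, 2.0, len(routes))
        stats = _stats_frame(rates, routes, rng=rng)
        res = DifferentialFiring(stats).fit("ranked_ancova")
        covs = stats[["mean_x", "mean_y", "mean_speed"]].to_numpy()
        f_oracle, p_oracle = brute_force_ranked_ancova(rates, covs, routes)
        assert abs(res.statistic - f_oracle) < 1e-8
        assert abs(res.p_value - p_oracle) < 1e-8


def test_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(2)
    routes = np.repeat([1, 2, 3, 4], 8)
    rates = rng.gamma(2.0, 2.0, len(routes))
    s1 = _stats_frame(rates, routes, rng=np.random.default_rng(3))
    s2 = s1.copy()
    s2["firing_rate"] = np.exp(s2["firing_rate"] / 3.0)
    f1 = DifferentialFiring(s1).fit("ranked_ancova").statistic
    f2 = DifferentialFiring(s2).fit("ranked_ancova").statistic
    assert f1 == pytest.approx(f2, abs=1e-10)


def test_constant_rate_yields_null_result():
    stats = _stats_frame([2.0] * 20, np.repeat([1, 2, 3, 4], 5))
    res = DifferentialFiring(stats).fit("ranked_ancova")
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.posthoc is None


def test_too_few_trials_rejected():
    stats = _stats_frame([1.0, 2.0, 3.0], [1, 1, 2])
    with pytest.raises(ValueError):
        DifferentialFiring(stats).fit("ranked_ancova")
    assert not DifferentialFiring(stats).eligible


# ---- permutation ANCOVA ----------------------------------------------


def test_permutation_p_zero_for_overwhelming_effect():
    rng = np.random.default_rng(4)
    routes = np.repeat([1, 2, 3, 4], 10)
    rates = np.where(routes == 2, 50.0, 1.0) + rng.normal(0, 0.1, len(routes))
    res = DifferentialFiring(_stats_frame(rates, routes, rng=rng)).fit(
        "permutation_ancova", k=500, seed=5
    )
    assert res.p_value == 0.0  # printed-formula edge: no shuffle reaches F_obs


def test_permutation_null_p_uniform():
    rng = np.random.default_rng(6)
    pvals = []
    routes = np.repeat([1, 2, 3, 4], 10)
    for _ in range(200):
        rates = rng.gamma(2.0, 2.0, len(routes))
        res = DifferentialFiring(_stats_frame(rates, routes, rng=rng)).fit(
            "permutation_ancova", k=199, seed=int(rng.integers(2**31))
        )
        pvals.append(res.p_value)
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_duplicating_trials_inflates_true_effect():
    rng = np.random.default_rng(7)
    routes = np.repeat([1, 2, 3, 4], 8)
    rates = np.where(routes == 3, 6.0, 2.0) + rng.normal(0, 1.0, len(routes))
    s1 = _stats_frame(rates, routes, rng=np.random.default_rng(8))
    s2 = pd.concat([s1, s1], ignore_index=True)
    s2["trial_id"] = np.arange(len(s2))
    f1 = DifferentialFiring(s1).fit("permutation_ancova", k=100, seed=1).statistic
    f2 = DifferentialFiring(s2).fit("permutation_ancova", k=100, seed=1).statistic
    assert f2 > f1


# ---- Poisson GLM ------------------------------------------------------


def test_glm_null_when_rates_equal():
    stats = _stats_frame([3.0] * 24, np.repeat([1, 2, 3, 4], 6), times=np.full(24, 2.0),
                         counts=[6] * 24)
    res = DifferentialFiring(stats).fit("poisson_glm")
    assert res.p_value > 0.9


def test_glm_doubling_rates_changes_only_intercept():
    import statsmodels.api as smapi

    rng = np.random.default_rng(9)
    routes = np.repeat([1, 2, 3, 4], 8)
    base = rng.poisson(8.0, len(routes)).astype(float)
    t = np.full(len(routes), 2.0)

    def fit(counts):
        s = _stats_frame(counts / t, routes, rng=np.random.default_rng(10),
                         counts=counts, times=t)
        X = np.column_stack(
            [np.ones(len(routes)), s[["mean_x", "mean_y", "mean_speed"]].to_numpy()]
            + [(routes == r).astype(float) for r in (2, 3, 4)]
        )
        return smapi.GLM(counts, X, family=smapi.families.Poisson(), offset=np.log(t)).fit()

    f1, f2 = fit(base), fit(2.0 * base)
    assert f2.params[0] - f1.params[0] == pytest.approx(np.log(2.0), abs=1e-6)
    np.testing.assert_allclose(f1.params[1:], f2.params[1:], atol=1e-6)


def test_glm_agrees_with_ranked_ancova_on_strong_effect(layout, route2_cell):
    _, _, stats = route2_cell
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = DifferentialFiring(stats).fit("ranked_ancova")
        r3 = DifferentialFiring(stats).fit("poisson_glm")
    assert r1.pattern() == r3.pattern() == "route_specific_2"


# ---- pattern classification ------------------------------------------


def test_classify_route_specific():
    res = _result_with(_posthoc_table([(1, 2), (1, 3), (1, 4)]))
    assert sm.classify_route_goal(res) == "route_specific_1"


def test_classify_goal_dependent():
    res = _result_with(_posthoc_table([(2, 1), (2, 4), (3, 1), (3, 4)]))
    assert sm.classify_route_goal(res) == "goal_dependent"


def test_classify_unclassified_cases():
    assert sm.classify_route_goal(_result_with(_posthoc_table([(1, 2)]))) == "unclassified"
    assert sm.classify_route_goal(_result_with(None)) == "unclassified"


# ---- population pattern chi-squares ----------------------------------


def test_pattern_chisquare_matches_exact_arithmetic():
    rng = np.random.default_rng(11)
    for _ in range(20):
        counts = {
            "route_specific_1": int(rng.integers(1, 30)),
            "route_specific_2": int(rng.integers(1, 30)),
            "route_specific_3": int(rng.integers(1, 30)),
            "route_specific_4": int(rng.integers(1, 30)),
            "goal_dependent": int(rng.integers(1, 30)),
        }
        out = sm.population_pattern_tests(counts)
        obs5 = out["five_category"]["observed"]
        assert out["five_category"]["statistic"] == pytest.approx(exact_chisquare(obs5))
        obs2 = out["centre_vs_outer"]["observed"]
        assert out["centre_vs_outer"]["statistic"] == pytest.approx(exact_chisquare(obs2))


def test_uniform_counts_give_zero_statistic():
    counts = {f"route_specific_{k}": 8 for k in (1, 2, 3, 4)}
    counts["goal_dependent"] = 8
    out = sm.population_pattern_tests(counts)
    assert out["five_category"]["statistic"] == pytest.approx(0.0)
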