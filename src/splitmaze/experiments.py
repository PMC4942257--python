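"""Reference synthetic experiments with known ground truth.

These functions wire the generator to the analyses under the study
conditions the task defines (11 rewarded trials per block, at least six
correct, four blocks covering the four routes, gain-4 route or goal
modulation) and are used both by the validation suite and by the
reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .behavior import confusion_pairs, score_blocks
from .differential import DifferentialFiring, sector_trial_stats
from .ensemble import RouteDecoder, pooled_decode
from .goalbox import GoalBoxSimilarity, boxroute_vectors
from .maze import build_maze_layout
from .simulate import CellSpec, ErrorModel, SessionConfig, simulate_place_cell, simulate_session

__all__ = [
    "clean_session",
    "start_box_cell",
    "type_one_error_rates",
    "pattern_recovery",
    "ensemble_experiment",
    "goalbox_experiment",
    "behavior_experiment",
]

METHODS = ("ranked_ancova", "permutation_ancova", "poisson_glm")


def _child_seeds(seed, n):
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def clean_session(seed, **config_kwargs):
    """One error-free win-stay session over the default 4-block schedule."""
    layout = build_maze_layout()
    config_kwargs.setdefault("error_model", ErrorModel(p_post=0.0))
    cfg = SessionConfig(seed=seed, **config_kwargs)
    traj, trials = simulate_session(layout, cfg)
    return layout, traj, trials


def start_box_cell(rng, route_gains=(1, 1, 1, 1), goal_gains=(1, 1, 1)):
    """A place cell whose field sits in the start box (where all four routes
    overlap), with the requested route/goal modulation."""
    return CellSpec(
        field_centers=(tuple(rng.uniform(-8.0, 8.0, 2)),),
        peak_rate=float(rng.uniform(2.0, 6.0)),
        route_gains=tuple(float(g) for g in route_gains),
        goal_gains=tuple(float(g) for g in goal_gains),
    )


def type_one_error_rates(seed, n_cells=1000, k=1000, alpha=0.05, methods=METHODS):
    """False-positive rate of each differential method on unmodulated cells.

    Every cell has a start-box field and identical firing statistics on all
    four routes; the returned rates should sit near the nominal alpha.
    """
    layout, traj, trials = clean_session(seed)
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    rejections = {m: 0 for m in methods}
    tested = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_cells):
            spec = start_box_cell(rng)
            st = simulate_place_cell(spec, traj, seed=int(rng.integers(2**31)))
            stats_df = sector_trial_stats(st, traj, trials, "start_box", layout)
            model = DifferentialFiring(stats_df, alpha=alpha)
            tested += 1
            for m in methods:
                res = model.fit(method=m, k=k, seed=int(rng.integers(2**31)))
                if res.p_value < alpha:
                    rejections[m] += 1
    return {m: rejections[m] / tested for m in methods}


def _generator_label(spec: CellSpec) -> str:
    gains = np.array([spec.effective_gain(r) for r in (1, 2, 3, 4)])
    if np.allclose(gains, gains[0]):
        return "none"
    if np.isclose(gains[1], gains[2]) and not np.isclose(gains[1], gains[0]) and np.isclose(gains[0], gains[3]):
        return "goal_dependent"
    distinct = [k for k in range(4) if all(not np.isclose(gains[k], gains[o]) for o in range(4) if o != k)]
    if len(distinct) == 1 and all(
        np.isclose(gains[o], gains[p]) for o in range(4) for p in range(4)
        if o != distinct[0] and p != distinct[0]
    ):
        return f"route_specific_{distinct[0] + 1}"
    return "other"


def pattern_recovery(seed, n_route=140, n_goal=60, gain=4.0, method="ranked_ancova"):
    """Classification of gain-modulated start-box cells against their
    generator labels.

    Returns overall accuracy, and the fraction of goal-dependent generator
    cells mislabelled as route-specific.
    """
    layout, traj, trials = clean_session(seed)
    rng = np.random.default_rng(_child_seeds(seed, 2)[1])
    n_correct = 0
    n_goal_seen = 0
    n_goal_as_route = 0
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_route + n_goal):
            if i < n_route:
                rg = [1.0] * 4
                rg[i % 4] = gain
                spec = start_box_cell(rng, route_gains=rg)
            else:
                spec = start_box_cell(rng, goal_gains=(1.0, gain, 1.0))
            truth = _generator_label(spec)
            st = simulate_place_cell(spec, traj, seed=int(rng.integers(2**31)))
            stats_df = sector_trial_stats(st, traj, trials, "start_box", layout)
            res = DifferentialFiring(stats_df).fit(method=method)
            label = res.pattern()
            records.append((truth, label))
            n_correct += label == truth
            if truth == "goal_dependent":
                n_goal_seen += 1
                n_goal_as_route += label.startswith("route_specific")
    return {
        "accuracy_pct": 100.0 * n_correct / (n_route + n_goal),
        "goal_mislabel_pct": 100.0 * n_goal_as_route / max(n_goal_seen, 1),
        "records": records,
    }


def _coded_ensemble(seed, coding, n_cells, gain):
    layout, traj, trials = clean_session(seed)
    rng = np.random.default_rng(seed + 90001)
    cells = {}
    for i in range(n_cells):
        if coding == "route":
            rg = [1.0] * 4
            rg[int(rng.integers(4))] = gain
            spec = start_box_cell(rng, route_gains=rg)
        elif coding == "goal":
            gg = [1.0] * 3
            gg[int(rng.integers(3))] = gain
            spec = start_box_cell(rng, goal_gains=gg)
        else:  # no coding: route-exchangeable
            spec = start_box_cell(rng)
        cells[f"c{i:03d}"] = simulate_place_cell(spec, traj, seed=int(rng.integers(2**31)))
    return layout, traj, trials, cells


def ensemble_experiment(
    seed,
    coding="route",
    n_sessions=25,
    n_cells=12,
    gain=4.0,
    sector="start_box",
    n_shuffles=2000,
):
    """Pooled population-vector decoding of simulated ensembles.

    ``coding='route'`` gives each cell one preferred route (the published
    situation); ``coding='goal'`` gives each cell one preferred goal so that
    routes 2 and 3 share their modulation (the alternative hypothesis).
    """
    decoders = []
    for s, child in enumerate(_child_seeds(seed, n_sessions)):
        layout, traj, trials, cells = _coded_ensemble(child, coding, n_cells, gain)
        decoders.append(
            RouteDecoder.from_session(cells, traj, trials, sector, layout)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pooled_decode(decoders, n_shuffles=n_shuffles, seed=seed)


def goalbox_experiment(seed, n_sessions=4, n_cells=60, n_shuffles=5000):
    """Goal-box similarity under route-invariant box firing.

    Each simulated unit is the union of two Poisson components: a broad
    goal-row field (so firing in the Centre box does not depend on the route
    taken there, and spatially adjacent boxes are represented more similarly
    than distant ones) and a route-modulated field near the start of the
    maze (route-dependent stem firing).  Only the Centre box R2/R3 pair
    should beat its shuffle null.
    """
    layout = build_maze_layout()
    goal_y = layout.route_paths[2][1][-1][1]
    half_span = abs(layout.route_paths[1][1][-1][0])
    sessions = []
    for child in _child_seeds(seed, n_sessions):
        _, traj, trials = clean_session(child)
        rng = np.random.default_rng(child + 77)
        cells = {}
        for i in range(n_cells):
            u = float(rng.uniform(-1.4 * half_span, 1.4 * half_span))
            box_spec = CellSpec(
                field_centers=((u, goal_y),),
                field_width=float(rng.uniform(35.0, 55.0)),
                peak_rate=float(rng.uniform(2.0, 8.0)),
                baseline_rate=float(rng.uniform(0.05, 0.4)),
            )
            rg = [1.0] * 4
            rg[int(rng.integers(4))] = 4.0
            stem_spec = start_box_cell(rng, route_gains=rg)
            st = np.sort(
                np.concatenate(
                    [
                        simulate_place_cell(box_spec, traj, seed=int(rng.integers(2**31))),
                        simulate_place_cell(stem_spec, traj, seed=int(rng.integers(2**31))),
                    ]
                )
            )
            cells[f"c{i:03d}"] = st
        sessions.append((cells, traj, trials))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vectors = boxroute_vectors(sessions, layout)
        return GoalBoxSimilarity(vectors).fit(n_shuffles=n_shuffles, seed=seed)


def behavior_experiment(seed, n_sessions=20, error_model=None):
    """Win-stay behavior over several sessions: travel times split at the
    first correct trial of each block, and the confusion-pair counts."""
    layout = build_maze_layout()
    pre, post, pairs = [], [], None
    for child in _child_seeds(seed, n_sessions):
        cfg = SessionConfig(seed=child, error_model=error_model or ErrorModel())
        _, trials = simulate_session(layout, cfg)
        blocks = score_blocks(trials)
        search = trials[trials["is_search"]]
        known = trials[~trials["is_search"]]
        pre.extend(search["duration"].tolist())
        post.extend(known["duration"].tolist())
        c = confusion_pairs(trials)
        pairs = c if pairs is None else pairs + c
    return {
        "mean_time_pre_s": float(np.mean(pre)),
        "mean_time_post_s": float(np.mean(post)),
        "confusion_pairs": pairs,
    }
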