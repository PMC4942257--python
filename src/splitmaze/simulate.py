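"""Synthetic win-stay sessions, trajectories, spike trains and feature clouds.

The generator realises the two competing hypotheses about differential place
cell firing: a cell's in-field intensity is multiplied by a per-route gain
(route coding) and/or a per-goal gain (goal coding, where the gain for the
Centre goal applies identically to routes 2 and 3).  Spikes are drawn from an
inhomogeneous Poisson process by thinning.  Behavior follows the win-stay,
lose-shift protocol: within a block the rat searches goal boxes until it
finds the rewarded one, then receives a fixed number of further rewarded
trials (with occasional confusion errors), and the reward moves to another
box for the next block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import GOALS, ROUTE_GOAL, MazeLayout

__all__ = [
    "ErrorModel",
    "SessionConfig",
    "CellSpec",
    "FeatureCloud",
    "simulate_session",
    "simulate_place_cell",
    "simulate_feature_cloud",
]

_GOAL_INDEX = {g: i for i, g in enumerate(GOALS)}


@dataclass(frozen=True)
class ErrorModel:
    """Choice-error structure of a session.

    Search errors (before the rewarded box is found) are structural: the rat
    samples unvisited goal boxes uniformly.  After identification each trial
    is an error with probability ``p_post``; the wrong route is drawn with
    weight ``centre_confusion_weight`` for the partner route to the Centre
    Goal Box (routes 2 and 3 are easily confused) and weight 1 otherwise.
    """

    p_post: float = 0.05
    centre_confusion_weight: float = 4.0


@dataclass(frozen=True)
class SessionConfig:
    n_blocks: int = 4
    trials_per_block: int = 11
    min_correct_per_block: int = 6
    route_schedule: tuple = (1, 2, 3, 4)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    inter_trial_hold: tuple = (6.0, 9.0)  # s, uniform range
    position_rate: float = 50.0  # Hz
    speed_run: float = 25.0  # cm/s once the rewarded box is known
    speed_search: float = 15.0  # cm/s during the search trials
    goal_dwell: tuple = (3.0, 5.0)  # s in the goal box on correct trials
    error_dwell: tuple = (1.0, 2.0)  # s at the goal on error trials
    seed: int | None = None

    def __post_init__(self):
        if self.trials_per_block < self.min_correct_per_block:
            raise ValueError("trials_per_block must be >= min_correct_per_block")
        if not self.route_schedule:
            raise ValueError("route_schedule must be nonempty")
        if any(r not in (1, 2, 3, 4) for r in self.route_schedule):
            raise ValueError("route_schedule values must be in {1, 2, 3, 4}")
        if self.position_rate <= 0:
            raise ValueError("position_rate must be positive")


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth firing model of one simulated place cell.

    intensity(t) = baseline + peak * exp(-d^2 / (2 w^2))
                   * route_gains[route(t)] * goal_gains[goal(route(t))]

    with d the distance to the nearest field centre and w the field width.
    """

    field_centers: tuple = ((0.0, 0.0),)
    field_width: float = 6.0  # cm
    peak_rate: float = 5.0  # Hz
    route_gains: tuple = (1.0, 1.0, 1.0, 1.0)
    goal_gains: tuple = (1.0, 1.0, 1.0)  # (left, centre, right)
    baseline_rate: float = 0.1  # Hz

    def __post_init__(self):
        if self.peak_rate < 0 or self.baseline_rate < 0 or self.field_width <= 0:
            raise ValueError("rates must be >= 0 and field_width > 0")
        if len(self.route_gains) != 4 or len(self.goal_gains) != 3:
            raise ValueError("route_gains has length 4, goal_gains length 3")
        if any(g < 0 for g in self.route_gains) or any(g < 0 for g in self.goal_gains):
            raise ValueError("gains must be >= 0")

    def effective_gain(self, route: int) -> float:
        return self.route_gains[route - 1] * self.goal_gains[_GOAL_INDEX[ROUTE_GOAL[route]]]


@dataclass(frozen=True)
class FeatureCloud:
    cluster_points: np.ndarray  # (n_c, d)
    noise_points: np.ndarray  # (m, d)
    cluster_mean: np.ndarray
    cluster_cov: np.ndarray
    noise_mean: np.ndarray
    separation: float


def _open_centre_route(rewarded_route: int) -> int:
    """Route to the Centre Goal Box whose entrance is not blocked."""
    if rewarded_route in (2, 3):
        return rewarded_route
    return 2 if rewarded_route == 1 else 3


def _goal_to_route(goal: str, rewarded_route: int) -> int:
    if goal == "left":
        return 1
    if goal == "right":
        return 4
    return _open_centre_route(rewarded_route)


def _smooth_noise(rng, n: int, rho: float = 0.9) -> np.ndarray:
    """AR(1) noise with unit marginal variance."""
    e = rng.standard_normal(n)
    out = np.empty(n)
    acc = e[0]
    for i in range(n):
        acc = rho * acc + np.sqrt(1 - rho**2) * e[i]
        out[i] = acc
    return out


def _polyline_arclen(points: np.ndarray):
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return seg, seglen, cum


def _interp_polyline(points: np.ndarray, s: np.ndarray):
    """Positions and unit tangents at arc lengths ``s`` along a polyline."""
    seg, seglen, cum = _polyline_arclen(points)
    s = np.clip(s, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seglen[idx]
    pos = points[idx] + frac[:, None] * seg[idx]
    tang = seg[idx] / seglen[idx][:, None]
    return pos, tang


def simulate_session(layout: MazeLayout, config: SessionConfig):
    """Simulate one win-stay session.

    Returns ``(trajectory, trials)``: a trajectory DataFrame with columns
    ``t, x, y, trial_id, route_id, phase`` and a trial table with one row per
    trial.  Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.position_rate
    start = np.asarray(layout.route_paths[1][1][0], float)

    traj_parts = []
    trial_rows = []
    t = 0.0
    trial_id = 0

    def emit_phase(duration, centre, jitter, clip, phase, route, tid, t0):
        n = max(1, int(round(duration / dt)))
        tt = t0 + dt * np.arange(n)
        xy = np.asarray(centre, float) + np.clip(
            rng.normal(0.0, jitter, (n, 2)), -clip, clip
        )
        traj_parts.append((tt, xy[:, 0], xy[:, 1], tid, route, phase))
        return t0 + n * dt

    def emit_run(route, speed_mean, tid, t0):
        points = layout.route_paths[route][1]
        _, _, cum = _polyline_arclen(points)
        L = cum[-1]
        v_trial = speed_mean * rng.lognormal(0.0, 0.12)
        n = max(2, int(round(L / v_trial / dt)))
        v = v_trial * np.clip(1.0 + 0.12 * _smooth_noise(rng, n), 0.2, None)
        s = np.concatenate([[0.0], np.cumsum(v[:-1]) * dt])
        s *= L / s[-1]
        pos, tang = _interp_polyline(points, s)
        lateral = np.clip(1.2 * _smooth_noise(rng, n), -3.2, 3.2)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        xy = pos + lateral[:, None] * normal
        tt = t0 + dt * np.arange(n)
        traj_parts.append((tt, xy[:, 0], xy[:, 1], tid, route, "run"))
        return t0 + n * dt

    for block, rewarded in enumerate(config.route_schedule[: config.n_blocks]):
        rewarded_goal = ROUTE_GOAL[rewarded]
        block_trials = []

        def run_trial(route, is_search, t, tid):
            correct = route == rewarded
            t_hold = t
            hold_dur = rng.uniform(*config.inter_trial_hold)
            t = emit_phase(hold_dur, start, 2.0, 8.0, "hold", route, tid, t)
            t_start = t
            speed = config.speed_search if is_search else config.speed_run
            t = emit_run(route, speed, tid, t)
            t_goal = t
            goal_centre = layout.route_paths[route][1][-1]
            dwell = rng.uniform(*(config.goal_dwell if correct else config.error_dwell))
            t = emit_phase(dwell, goal_centre, 2.5, 8.0, "goal", route, tid, t)
            trial_rows.append(
                dict(
                    trial_id=tid,
                    block=block,
                    route_id=route,
                    rewarded_route=rewarded,
                    correct=correct,
                    is_search=is_search,
                    t_hold_start=t_hold,
                    t_start=t_start,
                    t_goal=t_goal,
                    t_end=t,
                    duration=t_goal - t_start,
                )
            )
            block_trials.append(correct)
            return t

        # search: sample unvisited goal boxes until the rewarded one is found
        unvisited = list(GOALS)
        while True:
            goal = unvisited[rng.integers(len(unvisited))]
            route = _goal_to_route(goal, rewarded)
            t = run_trial(route, True, t, trial_id)
            trial_id += 1
            if goal == rewarded_goal:
                break
            unvisited.remove(goal)

        # post-identification: trials_per_block further trials, extended until
        # the minimum number of correct trials is reached
        n_post = 0
        n_correct = 0
        em = config.error_model
        while n_post < config.trials_per_block or n_correct < config.min_correct_per_block:
            if rng.random() < em.p_post:
                others = [r for r in (1, 2, 3, 4) if r != rewarded]
                partner = _open_centre_route(rewarded) if rewarded not in (2, 3) else (5 - rewarded)
                w = np.array(
                    [em.centre_confusion_weight if r == partner and rewarded in (2, 3) else 1.0 for r in others]
                )
                route = others[rng.choice(len(others), p=w / w.sum())]
            else:
                route = rewarded
            t = run_trial(route, False, t, trial_id)
            trial_id += 1
            n_post += 1
            if route == rewarded:
                n_correct += 1

    tt = np.concatenate([p[0] for p in traj_parts])
    traj = pd.DataFrame(
        {
            "t": tt,
            "x": np.concatenate([p[1] for p in traj_parts]),
            "y": np.concatenate([p[2] for p in traj_parts]),
            "trial_id": np.concatenate([np.full(len(p[0]), p[3]) for p in traj_parts]),
            "route_id": np.concatenate([np.full(len(p[0]), p[4]) for p in traj_parts]),
            "phase": np.concatenate([np.full(len(p[0]), p[5], dtype=object) for p in traj_parts]),
        }
    )
    trials = pd.DataFrame(trial_rows)
    trials["within_block_pos"] = trials.groupby("block").cumcount() + 1
    return traj, trials


def simulate_place_cell(spec: CellSpec, traj: pd.DataFrame, seed=None) -> np.ndarray:
    """Draw spike times from the cell's inhomogeneous Poisson intensity.

    Uses thinning with the exact upper bound
    ``baseline + peak * max(effective route gain)``; reproducible by seed.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    rng = np.random.default_rng(seed)
    t = traj["t"].to_numpy()
    xy = traj[["x", "y"]].to_numpy()
    routes = traj["route_id"].to_numpy()
    centers = np.asarray(spec.field_centers, float).reshape(-1, 2)
    gains = np.array([spec.effective_gain(r) for r in (1, 2, 3, 4)])

    lam_max = spec.baseline_rate + spec.peak_rate * gains.max()
    if lam_max <= 0:
        return np.empty(0)
    t0, t1 = t[0], t[-1]
    n_cand = rng.poisson(lam_max * (t1 - t0))
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, n_cand))

    cx = np.interp(cand, t, xy[:, 0])
    cy = np.interp(cand, t, xy[:, 1])
    idx = np.clip(np.searchsorted(t, cand, side="right") - 1, 0, len(t) - 1)
    croute = routes[idx].astype(int)

    d2 = np.min(
        (cx[:, None] - centers[None, :, 0]) ** 2 + (cy[:, None] - centers[None, :, 1]) ** 2,
        axis=1,
    )
    lam = spec.baseline_rate + spec.peak_rate * np.exp(
        -d2 / (2.0 * spec.field_width**2)
    ) * gains[croute - 1]
    keep = rng.uniform(0.0, lam_max, n_cand) < lam
    return cand[keep]


def intensity_at(spec: CellSpec, traj: pd.DataFrame) -> np.ndarray:
    """Programmed intensity (Hz) at each trajectory sample; test oracle for
    the thinning generator (expected count = integral of this over time)."""
    xy = traj[["x", "y"]].to_numpy()
    routes = traj["route_id"].to_numpy().astype(int)
    centers = np.asarray(spec.field_centers, float).reshape(-1, 2)
    gains = np.array([spec.effective_gain(r) for r in (1, 2, 3, 4)])
    d2 = np.min(
        (xy[:, 0][:, None] - centers[None, :, 0]) ** 2
        + (xy[:, 1][:, None] - centers[None, :, 1]) ** 2,
        axis=1,
    )
    return spec.baseline_rate + spec.peak_rate * np.exp(-d2 / (2.0 * spec.field_width**2)) * gains[
        routes - 1
    ]


def simulate_feature_cloud(
    n_c: int,
    n_noise: int,
    separation: float,
    dim: int = 8,
    seed=None,
) -> FeatureCloud:
    """Gaussian cluster plus a noise cloud displaced by ``separation``
    Mahalanobis units (w.r.t. the cluster covariance)."""
    if n_c <= dim:
        raise ValueError("n_c must exceed the feature dimension")
    if n_noise < 1:
        raise ValueError("n_noise must be >= 1")
    rng = np.random.default_rng(seed)
    mean = rng.normal(0.0, 5.0, dim)
    a = rng.normal(0.0, 1.0, (dim, dim))
    cov = a @ a.T / dim + 0.5 * np.eye(dim)
    chol = np.linalg.cholesky(cov)
    v = rng.standard_normal(dim)
    v /= np.linalg.norm(v)
    noise_mean = mean + separation * (chol @ v)
    cluster = rng.multivariate_normal(mean, cov, n_c)
    noise = rng.multivariate_normal(noise_mean, cov, n_noise)
    return FeatureCloud(
        cluster_points=cluster,
        noise_points=noise,
        cluster_mean=mean,
        cluster_cov=cov,
        noise_mean=noise_mean,
        separation=float(separation),
    )
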