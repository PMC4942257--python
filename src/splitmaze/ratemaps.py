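"""Occupancy-normalised kernel rate maps, spatial information and fields.

The rate estimate at a bin centre x is

    rate(x) = sum_i g(|s_i - x| / h)  /  sum_t g(|y_t - x| / h) * dt

with g(u) = exp(-u^2/2), spike positions s_i (linear time-interpolation of
the tracked path at spike times), path samples y_t, and smoothing factor h
(2.5 cm).  Bins with no path sample within the visit radius (5 cm) are
masked as never visited.  Spatial information is the occupancy-weighted
per-spike information sum P_i (R_i/R) log2(R_i/R), in bits per spike; the
occupancy probabilities P_i use raw (unsmoothed) dwell time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .maze import MazeLayout

__all__ = [
    "SmoothingParams",
    "RateMap",
    "gaussian_kernel",
    "spike_positions",
    "Occupancy",
    "compute_occupancy",
    "compute_rate_map",
    "spatial_information",
    "count_place_fields",
    "sector_activity_profile",
]


@dataclass(frozen=True)
class SmoothingParams:
    h: float = 2.5  # cm, kernel smoothing factor
    bin_size: float = 2.5  # cm
    visit_radius: float = 5.0  # cm

    def __post_init__(self):
        if min(self.h, self.bin_size, self.visit_radius) <= 0:
            raise ValueError("smoothing parameters must be positive")


@dataclass
class RateMap:
    x_centres: np.ndarray  # (nx,)
    y_centres: np.ndarray  # (ny,)
    rate: np.ndarray  # (ny, nx), NaN where unvisited
    occupancy: np.ndarray  # (ny, nx) kernel-weighted seconds (denominator)
    raw_occupancy: np.ndarray  # (ny, nx) dwell seconds by nearest bin
    visited: np.ndarray  # (ny, nx) bool
    params: SmoothingParams

    @property
    def peak_rate(self) -> float:
        r = self.rate[self.visited]
        return float(np.nanmax(r)) if r.size else 0.0

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate over visited bins (Hz)."""
        p = self.raw_occupancy[self.visited]
        if p.sum() <= 0:
            return 0.0
        return float(np.sum(p * self.rate[self.visited]) / p.sum())


def gaussian_kernel(u):
    """g(u) = exp(-u^2 / 2); even, g(0) = 1."""
    u = np.asarray(u, float)
    return np.exp(-0.5 * u**2)


def spike_positions(spike_times, traj: pd.DataFrame) -> np.ndarray:
    """(n, 2) spike positions by linear interpolation of the tracked path."""
    t = traj["t"].to_numpy()
    s = np.asarray(spike_times, float)
    return np.column_stack(
        [np.interp(s, t, traj["x"].to_numpy()), np.interp(s, t, traj["y"].to_numpy())]
    )


def _sample_dt(t: np.ndarray) -> np.ndarray:
    """Per-sample dwell times for the rectangle rule (forward differences,
    last sample repeating the previous interval)."""
    if len(t) < 2:
        return np.ones(len(t))
    d = np.diff(t)
    return np.concatenate([d, d[-1:]])


@dataclass
class Occupancy:
    """Session-level occupancy terms of the rate-map estimator, reusable
    across all cells of the session (the denominator does not depend on the
    cell)."""

    x_centres: np.ndarray
    y_centres: np.ndarray
    occupancy: np.ndarray  # kernel-weighted seconds per bin
    raw_occupancy: np.ndarray  # dwell seconds by nearest bin
    visited: np.ndarray
    params: SmoothingParams


def compute_occupancy(
    traj: pd.DataFrame,
    params: SmoothingParams = SmoothingParams(),
    layout: MazeLayout | None = None,
) -> Occupancy:
    """Kernel-weighted and raw occupancy plus the visit mask for a session.

    The grid covers the maze bounding box when a layout is given, otherwise
    the trajectory bounding box padded by the visit radius.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    t = traj["t"].to_numpy()
    pxy = traj[["x", "y"]].to_numpy()
    if layout is not None:
        x0, y0, x1, y1 = layout.bounding_box()
    else:
        pad = params.visit_radius
        x0, y0 = pxy.min(axis=0) - pad
        x1, y1 = pxy.max(axis=0) + pad
    b = params.bin_size
    nx = max(1, int(np.ceil((x1 - x0) / b)))
    ny = max(1, int(np.ceil((y1 - y0) / b)))
    xc = x0 + b * (np.arange(nx) + 0.5)
    yc = y0 + b * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xc, yc)
    centres = np.column_stack([gx.ravel(), gy.ravel()])

    dt = _sample_dt(t)
    occ = _kernel_sums(centres, pxy, params.h, weights=dt)
    dist, _ = cKDTree(pxy).query(centres, k=1)
    visited = (dist <= params.visit_radius).reshape(ny, nx)

    ix = np.clip(((pxy[:, 0] - x0) // b).astype(int), 0, nx - 1)
    iy = np.clip(((pxy[:, 1] - y0) // b).astype(int), 0, ny - 1)
    raw = np.zeros((ny, nx))
    np.add.at(raw, (iy, ix), dt)
    return Occupancy(xc, yc, occ.reshape(ny, nx), raw, visited, params)


def _kernel_sums(centres, points, h, weights=None):
    """sum_j w_j g(|p_j - c| / h) for every grid centre c, in chunks."""
    out = np.zeros(len(centres))
    if len(points) == 0:
        return out
    chunk = max(1, int(2e7 // len(points)))
    for i in range(0, len(centres), chunk):
        c = centres[i : i + chunk]
        d2 = (c[:, None, 0] - points[None, :, 0]) ** 2 + (c[:, None, 1] - points[None, :, 1]) ** 2
        g = np.exp(-0.5 * d2 / h**2)
        out[i : i + chunk] = g @ weights if weights is not None else g.sum(axis=1)
    return out


def compute_rate_map(
    spike_times,
    traj: pd.DataFrame,
    params: SmoothingParams = SmoothingParams(),
    layout: MazeLayout | None = None,
    occupancy: Occupancy | None = None,
) -> RateMap:
    """Kernel rate map of one cell over the session.

    Pass a precomputed :func:`compute_occupancy` result to reuse the
    denominator across the cells of a session.
    """
    if occupancy is None:
        occupancy = compute_occupancy(traj, params, layout)
    params = occupancy.params
    spos = spike_positions(spike_times, traj)
    gx, gy = np.meshgrid(occupancy.x_centres, occupancy.y_centres)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    num = _kernel_sums(centres, spos, params.h).reshape(occupancy.occupancy.shape)

    visited = occupancy.visited
    rate = np.full(visited.shape, np.nan)
    rate[visited] = num[visited] / occupancy.occupancy[visited]
    return RateMap(
        occupancy.x_centres,
        occupancy.y_centres,
        rate,
        occupancy.occupancy,
        occupancy.raw_occupancy,
        visited,
        params,
    )


def spatial_information(rate_map: RateMap) -> float:
    """Skaggs spatial information of the map, in bits per spike.

    Returns 0 for an all-zero map (no spikes carry no information); uses the
    convention 0*log(0) = 0.  Always >= 0 by Jensen's inequality.
    """
    v = rate_map.visited
    p = rate_map.raw_occupancy[v]
    r = rate_map.rate[v]
    if p.sum() <= 0:
        return 0.0
    p = p / p.sum()
    mean_rate = np.sum(p * r)
    if mean_rate <= 0:
        return 0.0
    rel = r / mean_rate
    pos = rel > 0
    return float(np.sum(p[pos] * rel[pos] * np.log2(rel[pos])))


def count_place_fields(
    rate_map: RateMap,
    threshold_fraction: float = 0.2,
    min_bins: int = 4,
):
    """Number of distinguishable place fields and their bin masks.

    A field is a 4-connected component of visited bins with rate at or above
    ``threshold_fraction`` of the map peak, spanning at least ``min_bins``
    bins.
    """
    peak = rate_map.peak_rate
    if peak <= 0:
        return 0, np.zeros_like(rate_map.visited, dtype=int)
    mask = rate_map.visited & (np.nan_to_num(rate_map.rate) >= threshold_fraction * peak)
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    keep = 0
    out = np.zeros_like(labels)
    for lab in range(1, n + 1):
        m = labels == lab
        if m.sum() >= min_bins:
            keep += 1
            out[m] = keep
    return keep, out


def sector_activity_profile(
    cells: dict,
    traj: pd.DataFrame,
    layout: MazeLayout,
    active_threshold: float = 1.0,
):
    """Per-sector activity profile of a cell population.

    A cell is active in a sector when its pooled firing rate there exceeds
    ``active_threshold`` Hz on at least one route.  Returns the 14-row
    profile DataFrame and the Pearson correlation (r, p, df = n-2) between a
    sector's distance rank from the start box and its active-cell count.
    """
    if not cells:
        raise ValueError("need at least one cell")
    t = traj["t"].to_numpy()
    dt = _sample_dt(t)
    sec = layout.assign_sectors(traj["x"].to_numpy(), traj["y"].to_numpy())
    routes = traj["route_id"].to_numpy().astype(int)
    step = np.concatenate([np.hypot(np.diff(traj["x"]), np.diff(traj["y"])), [0.0]])

    names = layout.names
    n_sec = len(names)
    time_sr = np.zeros((n_sec, 4))
    dist_sr = np.zeros((n_sec, 4))
    for s in range(n_sec):
        for r in range(4):
            m = (sec == s) & (routes == r + 1)
            time_sr[s, r] = dt[m].sum()
            dist_sr[s, r] = step[m].sum()

    spike_sector_route = {}
    for cid, st in cells.items():
        spos = spike_positions(st, traj)
        ssec = layout.assign_sectors(spos[:, 0], spos[:, 1])
        idx = np.clip(np.searchsorted(t, np.asarray(st, float), side="right") - 1, 0, len(t) - 1)
        sroute = routes[idx]
        cnt = np.zeros((n_sec, 4))
        for s, r in zip(ssec, sroute):
            if s >= 0:
                cnt[s, r - 1] += 1
        spike_sector_route[cid] = cnt

    rows = []
    for s, name in enumerate(names):
        with np.errstate(invalid="ignore", divide="ignore"):
            active = 0
            mean_rates = []
            for cid in cells:
                rates = np.where(time_sr[s] > 0, spike_sector_route[cid][s] / np.where(time_sr[s] > 0, time_sr[s], 1.0), 0.0)
                if np.any(rates > active_threshold):
                    active += 1
                tot_t = time_sr[s].sum()
                mean_rates.append(spike_sector_route[cid][s].sum() / tot_t if tot_t > 0 else 0.0)
        tot_t = time_sr[s].sum()
        rows.append(
            dict(
                sector=name,
                distance_rank=layout.sector_order[name],
                n_active=active,
                mean_rate=float(np.mean(mean_rates)),
                mean_speed=float(dist_sr[s].sum() / tot_t) if tot_t > 0 else np.nan,
                occupancy_s=float(tot_t),
            )
        )
    profile = pd.DataFrame(rows)
    r, p = stats.pearsonr(profile["distance_rank"], profile["n_active"])
    return profile, (float(r), float(p), len(profile) - 2)
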