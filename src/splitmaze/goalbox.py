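"""Route invariance of Centre Goal Box firing.

Four population vectors are built from the destination-box firing rates of
all pooled place cells: the Left box at the end of Route 1, the Centre box
at the end of Routes 2 and 3, and the Right box at the end of Route 4.  If
the Centre Goal Box is represented as a single place, the two Centre
vectors should be more highly Spearman-correlated than any other pair, and
more highly than a null in which each cell's rate is drawn at random from
its rates under the other route labels (route identity shuffled, cell order
kept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .differential import sector_trial_stats
from .maze import MazeLayout
from .stats import epanechnikov_bandwidth, smoothed_cdf

__all__ = [
    "BOX_LABELS",
    "boxroute_vectors",
    "boxroute_correlations",
    "GoalBoxSimilarity",
    "GoalBoxResults",
]

#: the four destination-box / route combinations
BOX_LABELS = ("left_r1", "centre_r2", "centre_r3", "right_r4")
_LABEL_ROUTE = {"left_r1": 1, "centre_r2": 2, "centre_r3": 3, "right_r4": 4}


def boxroute_vectors(
    sessions,
    layout: MazeLayout,
    include_errors: bool = False,
) -> pd.DataFrame:
    """Pooled cells x 4 matrix of destination-box firing rates.

    ``sessions`` is an iterable of ``(cells, traj, trials)`` tuples where
    ``cells`` maps cell id to spike times; cells from different sessions are
    concatenated (each cell-session is one row).  Entry (cell, label) is the
    cell's mean rate in the label's goal box over trials of that route.
    """
    rows = {}
    for si, (cells, traj, trials) in enumerate(sessions):
        for label, route in _LABEL_ROUTE.items():
            box = layout.goal_box_sector(route)
            sub = trials[trials["route_id"] == route]
            for cid, st in cells.items():
                stats_df = sector_trial_stats(
                    st, traj, sub, box, layout, include_errors=include_errors
                )
                key = (si, cid)
                rows.setdefault(key, {})[label] = (
                    stats_df["n_spikes"].sum() / stats_df["time_in_sector"].sum()
                    if len(stats_df) and stats_df["time_in_sector"].sum() > 0
                    else np.nan
                )
    out = pd.DataFrame.from_dict(rows, orient="index")[list(BOX_LABELS)]
    dropped = int(out.isna().any(axis=1).sum())
    if dropped:
        warnings.warn(f"{dropped} cell(s) never sampled in some goal box; excluded")
    return out.dropna()


def boxroute_correlations(vectors: pd.DataFrame) -> pd.Series:
    """Spearman rho for each unordered pair of the four box/route vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least two cells")
    out = {}
    for a, b in combinations(vectors.columns, 2):
        va, vb = vectors[a], vectors[b]
        if va.nunique() < 2 or vb.nunique() < 2:
            warnings.warn(f"constant vector in pair ({a}, {b}); rho undefined")
            out[(a, b)] = np.nan
            continue
        rho, _ = sps.spearmanr(va, vb)
        out[(a, b)] = float(rho)
    return pd.Series(out, name="rho")


@dataclass
class GoalBoxResults:
    rho: pd.Series  # six pairwise Spearman correlations
    p: pd.Series  # shuffle-percentile probabilities per pair
    n_cells: int
    n_shuffles: int

    def summary(self) -> str:
        tab = pd.DataFrame({"rho": self.rho, "p": self.p})
        return "\n".join(
            [
                "Goal-box population-vector similarity",
                "=" * 40,
                f"cells pooled : {self.n_cells}",
                f"shuffles     : {self.n_shuffles}",
                tab.round(4).to_string(),
            ]
        )


class GoalBoxSimilarity:
    """Model of pairwise goal-box population-vector similarity.

    Built from the cells x 4 rate matrix of :func:`boxroute_vectors`;
    ``fit`` computes the six Spearman correlations and their shuffle-null
    probabilities (Epanechnikov-smoothed CDF percentile).
    """

    def __init__(self, vectors: pd.DataFrame, min_cells: int = 10):
        if len(vectors) < min_cells:
            raise ValueError(f"need at least {min_cells} cells, got {len(vectors)}")
        self.vectors = vectors[list(BOX_LABELS)]

    def fit(self, n_shuffles: int = 10000, seed=None, bandwidth=None) -> GoalBoxResults:
        if n_shuffles < 100:
            warnings.warn("fewer than 100 shuffles gives unstable p-values")
        rng = np.random.default_rng(seed)
        V = self.vectors.to_numpy(float)
        n = len(V)
        rho = boxroute_correlations(self.vectors)
        cols = list(self.vectors.columns)

        def tail_p(ia, obs):
            """P(shuffle rho >= obs) for anchor vector ``ia``: the anchor is
            correlated with a vector whose entry per cell is one of that
            cell's rates under the three other labels (cell order kept)."""
            others = [j for j in range(4) if j != ia]
            pick = rng.integers(0, 3, size=(n_shuffles, n))
            shuffled = V[np.arange(n)[None, :], np.asarray(others)[pick]]
            ra = sps.rankdata(V[:, ia])
            rs = sps.rankdata(shuffled, axis=1)
            ra_c = ra - ra.mean()
            rs_c = rs - rs.mean(axis=1, keepdims=True)
            denom = np.linalg.norm(ra_c) * np.linalg.norm(rs_c, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                rho_shuff = (rs_c @ ra_c) / denom
            rho_shuff = rho_shuff[np.isfinite(rho_shuff)]
            if len(rho_shuff) == 0:
                return np.nan
            bw = bandwidth if bandwidth is not None else epanechnikov_bandwidth(rho_shuff)
            return float(np.clip(1.0 - smoothed_cdf(obs, rho_shuff, bw), 0.0, 1.0))

        # the pair is unordered: anchor the shuffle on each box in turn and
        # call the pair above chance only if it is from both perspectives
        p = {}
        for a, b in combinations(cols, 2):
            obs = rho[(a, b)]
            if not np.isfinite(obs):
                p[(a, b)] = np.nan
                continue
            p[(a, b)] = max(tail_p(cols.index(a), obs), tail_p(cols.index(b), obs))
        return GoalBoxResults(
            rho=rho, p=pd.Series(p, name="p"), n_cells=n, n_shuffles=n_shuffles
        )
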