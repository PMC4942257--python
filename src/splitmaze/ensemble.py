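"""Leave-one-out population-vector decoding of routes by cosine similarity.

Each trial's population vector (ensemble firing rates in the start box or
central stem) is matched to the most similar of four route-average "goal"
vectors, computed with the trial held out of its own route's average.  The
chance level of the resulting match percentages is assessed against a null
in which the four goal-vector entries of each neuron are independently
permuted across routes (route identity shuffled, neuron identity kept),
with p-values read off an Epanechnikov-smoothed CDF of the shuffle
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .differential import sector_trial_stats
from .maze import MazeLayout
from .stats import shuffle_pvalue

__all__ = [
    "cosine_similarity",
    "trial_population_vectors",
    "goal_population_vectors",
    "RouteDecoder",
    "DecodingResults",
    "pooled_decode",
    "within_block_trend",
]

ROUTES = (1, 2, 3, 4)


def cosine_similarity(x, y) -> float:
    """<x, y> / (|x| |y|); in [0, 1] for nonnegative rate vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("population vectors have mismatched dimensions")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("cosine similarity undefined for a zero population vector")
        return float("nan")
    return float(np.dot(x, y) / (nx * ny))


def trial_population_vectors(
    cells: dict,
    traj: pd.DataFrame,
    trials: pd.DataFrame,
    sector: str,
    layout: MazeLayout,
    include_errors: bool = False,
):
    """Per-trial ensemble rate matrix (trials x cells) in one sector.

    Error trials are omitted by default (the few errors made during
    recording are excluded from the ensemble analysis).  Returns
    ``(rates, routes)`` aligned on trial id.
    """
    cols = {}
    for cid, st in cells.items():
        stats_df = sector_trial_stats(
            st, traj, trials, sector, layout, include_errors=include_errors
        )
        cols[cid] = stats_df.set_index("trial_id")["firing_rate"]
    rates = pd.DataFrame(cols).dropna()
    routes = trials.set_index("trial_id").loc[rates.index, "route_id"].astype(int)
    return rates, routes


def goal_population_vectors(
    rates: pd.DataFrame,
    routes: pd.Series,
    held_out_trial=None,
) -> pd.DataFrame:
    """Four route-average population vectors, excluding ``held_out_trial``
    from its own route's average.  Routes left with fewer than two trials
    are excluded with a warning."""
    rows = {}
    for r in ROUTES:
        idx = routes.index[routes == r]
        if held_out_trial is not None and held_out_trial in idx:
            idx = idx.drop(held_out_trial)
        if len(idx) < 2:
            warnings.warn(f"route {r} has fewer than 2 trials; goal vector excluded")
            continue
        rows[r] = rates.loc[idx].mean(axis=0)
    return pd.DataFrame(rows).T


@dataclass
class DecodingResults:
    """Match percentages, shuffle p-values and the per-trial decode log."""

    match_matrix: pd.DataFrame  # 4x4, rows = trajectory route, % per goal vector
    p_matrix: pd.DataFrame  # 4x4 shuffle-percentile probabilities
    decode_log: pd.DataFrame  # trial, route, sim_1..sim_4, match, correct
    n_shuffles: int
    n_skipped: int
    shuffle_distributions: np.ndarray | None = None  # (n_shuffles, 4, 4)

    @property
    def percent_correct(self) -> float:
        return float(100.0 * self.decode_log["correct"].mean())

    def summary(self) -> str:
        lines = [
            "Population-vector route decoding",
            "=" * 40,
            f"trials decoded    : {len(self.decode_log)} (skipped {self.n_skipped})",
            f"correct matches   : {self.percent_correct:.1f}%",
            f"shuffles          : {self.n_shuffles}",
            "match matrix (% of row-route trials matched to each goal vector):",
            self.match_matrix.round(1).to_string(),
            "shuffle p-values:",
            self.p_matrix.map(lambda v: f"{v:.3g}").to_string(),
        ]
        return "\n".join(lines)


class RouteDecoder:
    """Decoder of the animal's route from ensemble activity in one sector.

    Parameters
    ----------
    rates : DataFrame
        Trials x cells firing-rate matrix (one sector).
    routes : Series
        Route id (1-4) per trial, aligned with ``rates``.
    min_cells : int
        Ensembles below this size are rejected (default 6).
    trial_info : DataFrame, optional
        Extra per-trial columns (e.g. ``within_block_pos``) carried into the
        decode log for the within-block trend check.
    """

    def __init__(self, rates: pd.DataFrame, routes, min_cells: int = 6, trial_info=None):
        self.rates = rates
        self.routes = pd.Series(routes, index=rates.index).astype(int)
        if rates.shape[1] < min_cells:
            raise ValueError(
                f"ensemble of {rates.shape[1]} cells is below the minimum of {min_cells}"
            )
        self.trial_info = trial_info

    @classmethod
    def from_session(
        cls, cells, traj, trials, sector, layout, min_cells: int = 6, include_errors=False
    ):
        rates, routes = trial_population_vectors(
            cells, traj, trials, sector, layout, include_errors=include_errors
        )
        info_cols = [c for c in ("within_block_pos", "block") if c in trials.columns]
        info = trials.set_index("trial_id").loc[rates.index, info_cols] if info_cols else None
        return cls(rates, routes, min_cells=min_cells, trial_info=info)

    def _loo_goal_tensor(self):
        """(T, 4, C) leave-one-out goal vectors; NaN rows for routes with
        fewer than 2 contributing trials."""
        R = self.rates.to_numpy(float)
        routes = self.routes.to_numpy()
        T, C = R.shape
        G = np.full((T, 4, C), np.nan)
        for gi, r in enumerate(ROUTES):
            m = routes == r
            n = m.sum()
            if n == 0:
                continue
            total = R[m].sum(axis=0)
            mean_all = total / n
            for i in range(T):
                if m[i]:
                    if n >= 2:
                        G[i, gi] = (total - R[i]) / (n - 1)
                else:
                    if n >= 1:
                        G[i, gi] = mean_all
        return G

    @staticmethod
    def _decode(Xn, G, rng=None):
        """Row-normalised trial vectors against a (T, 4, C) goal tensor;
        returns (similarities (T,4), matched goal index (T,))."""
        Gn = np.linalg.norm(G, axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.einsum("tc,tgc->tg", Xn, G) / Gn
        sims = np.where(np.isfinite(sims), sims, -np.inf)
        if rng is None:
            match = np.argmax(sims, axis=1)
        else:
            # random tie-break among exact argmax ties
            best = sims.max(axis=1, keepdims=True)
            match = np.array(
                [rng.choice(np.flatnonzero(row)) for row in (sims == best)]
            )
        return sims, match

    @staticmethod
    def _match_matrix(routes_idx, match, valid):
        out = np.full((4, 4), np.nan)
        for gi in range(4):
            m = (routes_idx == gi) & valid
            if m.sum() == 0:
                continue
            out[gi] = 100.0 * np.bincount(match[m], minlength=4) / m.sum()
        return out

    def fit(
        self,
        n_shuffles: int = 10000,
        seed=None,
        bandwidth: float | None = None,
        keep_shuffles: bool = False,
    ) -> DecodingResults:
        if n_shuffles < 100:
            warnings.warn("fewer than 100 shuffles gives unstable p-values")
        rng = np.random.default_rng(seed)
        R = self.rates.to_numpy(float)
        routes = self.routes.to_numpy()
        routes_idx = routes - 1
        T, C = R.shape
        G = self._loo_goal_tensor()

        norms = np.linalg.norm(R, axis=1)
        valid = norms > 0
        n_skipped = int((~valid).sum())
        Xn = np.zeros_like(R)
        Xn[valid] = R[valid] / norms[valid, None]

        sims, match = self._decode(Xn, G, rng=rng)
        obs = self._match_matrix(routes_idx, match, valid)

        shuff = np.empty((n_shuffles, 4, 4))
        for s in range(n_shuffles):
            perms = rng.permuted(np.tile(np.arange(4)[:, None], (1, C)), axis=0)
            Gs = np.take_along_axis(G, perms[None, :, :], axis=1)
            _, m = self._decode(Xn, Gs)
            shuff[s] = self._match_matrix(routes_idx, m, valid)

        p = np.full((4, 4), np.nan)
        for r in range(4):
            for g in range(4):
                if np.isfinite(obs[r, g]):
                    dist = shuff[:, r, g]
                    dist = dist[np.isfinite(dist)]
                    if len(dist):
                        p[r, g] = shuffle_pvalue(obs[r, g], dist, bandwidth)

        idx = pd.Index(ROUTES, name="trajectory_route")
        cols = pd.Index(ROUTES, name="goal_vector_route")
        log = pd.DataFrame(
            {
                "trial_id": self.rates.index,
                "route_id": routes,
                **{f"sim_{r}": sims[:, r - 1] for r in ROUTES},
                "match": match + 1,
                "correct": (match == routes_idx) & valid,
                "valid": valid,
            }
        ).set_index("trial_id")
        log["match_similarity"] = sims[np.arange(T), match]
        if self.trial_info is not None:
            log = log.join(self.trial_info)
        return DecodingResults(
            match_matrix=pd.DataFrame(obs, index=idx, columns=cols),
            p_matrix=pd.DataFrame(p, index=idx, columns=cols),
            decode_log=log[log["valid"]].drop(columns="valid"),
            n_shuffles=n_shuffles,
            n_skipped=n_skipped,
            shuffle_distributions=shuff if keep_shuffles else None,
        )


def pooled_decode(
    decoders,
    n_shuffles: int = 10000,
    seed=None,
    bandwidth: float | None = None,
    keep_shuffles: bool = False,
) -> DecodingResults:
    """Decode several sessions' ensembles and pool the match percentages.

    The observed tile (r, g) is the percentage of all route-r trials across
    sessions matched to goal vector g; each shuffle draws fresh independent
    per-neuron route permutations in every session before pooling, which is
    what makes the pooled percentages continuous enough for tail p-values.
    """
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives unstable p-values")
    rng = np.random.default_rng(seed)
    prepped = []
    logs = []
    for dec in decoders:
        R = dec.rates.to_numpy(float)
        routes_idx = dec.routes.to_numpy() - 1
        norms = np.linalg.norm(R, axis=1)
        valid = norms > 0
        Xn = np.zeros_like(R)
        Xn[valid] = R[valid] / norms[valid, None]
        G = dec._loo_goal_tensor()
        prepped.append((Xn, G, routes_idx, valid, R.shape[1]))

    def counts(Xn, G, routes_idx, valid):
        _, match = RouteDecoder._decode(Xn, G)
        c = np.zeros((4, 4))
        for gi in range(4):
            m = (routes_idx == gi) & valid
            if m.any():
                c[gi] += np.bincount(match[m], minlength=4)
        return c

    obs_counts = np.zeros((4, 4))
    n_skipped = 0
    for si, (Xn, G, routes_idx, valid, C) in enumerate(prepped):
        sims, match = RouteDecoder._decode(Xn, G, rng=rng)
        n_skipped += int((~valid).sum())
        dec = decoders[si]
        log = pd.DataFrame(
            {
                "session": si,
                "trial_id": dec.rates.index,
                "route_id": routes_idx + 1,
                **{f"sim_{r}": sims[:, r - 1] for r in ROUTES},
                "match": match + 1,
                "correct": (match == routes_idx) & valid,
                "valid": valid,
            }
        )
        log["match_similarity"] = sims[np.arange(len(match)), match]
        if dec.trial_info is not None:
            log = log.join(dec.trial_info.reset_index(drop=True))
        logs.append(log[log["valid"]].drop(columns="valid"))
        for gi in range(4):
            m = (routes_idx == gi) & valid
            if m.any():
                obs_counts[gi] += np.bincount(match[m], minlength=4)

    def to_pct(c):
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * c / c.sum(axis=1, keepdims=True)

    obs = to_pct(obs_counts)
    shuff = np.empty((n_shuffles, 4, 4))
    for s in range(n_shuffles):
        c = np.zeros((4, 4))
        for Xn, G, routes_idx, valid, C in prepped:
            perms = rng.permuted(np.tile(np.arange(4)[:, None], (1, C)), axis=0)
            Gs = np.take_along_axis(G, perms[None, :, :], axis=1)
            c += counts(Xn, Gs, routes_idx, valid)
        shuff[s] = to_pct(c)

    p = np.full((4, 4), np.nan)
    for r in range(4):
        for g in range(4):
            if np.isfinite(obs[r, g]):
                dist = shuff[:, r, g]
                dist = dist[np.isfinite(dist)]
                if len(dist):
                    p[r, g] = shuffle_pvalue(obs[r, g], dist, bandwidth)

    idx = pd.Index(ROUTES, name="trajectory_route")
    cols = pd.Index(ROUTES, name="goal_vector_route")
    return DecodingResults(
        match_matrix=pd.DataFrame(obs, index=idx, columns=cols),
        p_matrix=pd.DataFrame(p, index=idx, columns=cols),
        decode_log=pd.concat(logs, ignore_index=True),
        n_shuffles=n_shuffles,
        n_skipped=n_skipped,
        shuffle_distributions=shuff if keep_shuffles else None,
    )


def within_block_trend(decode_log: pd.DataFrame, max_position: int = 12):
    """Rank correlation of within-block trial position with (a) the
    correct-match indicator and (b) the cosine similarity of the matched
    goal vector.  Positions beyond the mean block length are truncated.
    """
    if "within_block_pos" not in decode_log.columns:
        raise ValueError("decode log lacks within_block_pos")
    d = decode_log[decode_log["within_block_pos"] <= max_position]
    if d["within_block_pos"].nunique() < 3:
        return {"flag": "fewer than 3 distinct block positions"}
    sim_correct = np.array(
        [row[f"sim_{int(row['route_id'])}"] for _, row in d.iterrows()]
    )
    out = {}
    for name, vals in (
        ("correct_match", d["correct"].astype(float).to_numpy()),
        ("similarity", sim_correct),
    ):
        if np.ptp(vals) == 0:
            out[name] = dict(rho=0.0, p=1.0)
        else:
            rho, p = sps.spearmanr(d["within_block_pos"], vals)
            out[name] = dict(rho=float(rho), p=float(p))
    return out
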