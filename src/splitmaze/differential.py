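"""Trial-wise differential firing tests with covariate control.

For every place cell active in a scored maze sector, per-trial firing rates
are tested for modulation by route while controlling for the trial's mean
position and running speed.  Three methods are provided behind one
Model/Results interface:

``ranked_ancova``
    Rank-transform the rate and the covariates, regress ranked rate on
    ranked covariates, and run a one-way ANOVA of the residuals against
    route; post-hoc, six pairwise comparisons of the residual marginal means
    (Tukey-Kramer by default).
``permutation_ancova``
    Parametric ANCOVA partial F for the route term, with a permutation
    p-value p = #(F_shuffled >= F_observed) / k from shuffling the rates
    against fixed route/covariates.
``poisson_glm``
    Log-link Poisson regression of per-trial spike counts (log-exposure
    offset) on route and covariates, likelihood-ratio omnibus test, and six
    Mann-Whitney post-hoc comparisons of raw rates.

Cells whose omnibus test is significant are classified as route-specific
(one route differs from each of the other three) or goal-dependent (routes
2 and 3, which share the Centre Goal Box, each differ from routes 1 and 4
but not from each other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .maze import MazeLayout
from .ratemaps import _sample_dt, spike_positions

__all__ = [
    "TrialSectorStats",
    "sector_trial_stats",
    "is_active_in_sector",
    "DifferentialFiring",
    "DifferentialFiringResults",
    "classify_route_goal",
    "population_pattern_tests",
]

ROUTE_PAIRS = tuple(combinations((1, 2, 3, 4), 2))
COVARIATES = ("mean_x", "mean_y", "mean_speed")

PATTERN_LABELS = (
    "route_specific_1",
    "route_specific_2",
    "route_specific_3",
    "route_specific_4",
    "goal_dependent",
    "unclassified",
)


@dataclass(frozen=True)
class TrialSectorStats:
    trial_id: int
    route_id: int
    firing_rate: float
    mean_x: float
    mean_y: float
    mean_speed: float
    time_in_sector: float
    n_spikes: int


def sector_trial_stats(
    spike_times,
    traj: pd.DataFrame,
    trials: pd.DataFrame,
    sector,
    layout: MazeLayout | None = None,
    include_errors: bool = False,
) -> pd.DataFrame:
    """Per-trial firing rate, mean position and mean speed in one sector.

    ``sector`` is a sector name (requires ``layout``) or a shapely polygon.
    One row per trial that traverses the sector; error trials are excluded
    unless ``include_errors``.  Rates are spikes-in-sector over seconds in
    sector; speed is path length in sector over time there.  Spike positions
    come from linear interpolation of the path at spike times, and sector
    membership of spikes follows the same half-open boundary convention as
    position samples.
    """
    if isinstance(sector, str):
        if layout is None:
            raise ValueError("a layout is required to look up a sector by name")
        poly = layout.sectors[sector]
    else:
        poly = sector

    t = traj["t"].to_numpy()
    x = traj["x"].to_numpy()
    y = traj["y"].to_numpy()
    tid = traj["trial_id"].to_numpy().astype(int)
    dt = _sample_dt(t)
    inside = shapely.intersects_xy(poly, x, y)
    step = np.concatenate([np.hypot(np.diff(x), np.diff(y)), [0.0]])

    st = np.asarray(spike_times, float)
    spos = spike_positions(st, traj)
    s_inside = shapely.intersects_xy(poly, spos[:, 0], spos[:, 1])
    s_idx = np.clip(np.searchsorted(t, st, side="right") - 1, 0, len(t) - 1)
    s_tid = tid[s_idx]

    rows = []
    wanted = trials if include_errors else trials[trials["correct"]]
    for tr in wanted.itertuples():
        m = inside & (tid == tr.trial_id)
        time_in = dt[m].sum()
        if time_in <= 0:
            continue
        n_sp = int(np.sum(s_inside & (s_tid == tr.trial_id)))
        rows.append(
            dict(
                trial_id=int(tr.trial_id),
                route_id=int(tr.route_id),
                firing_rate=n_sp / time_in,
                mean_x=float(x[m].mean()),
                mean_y=float(y[m].mean()),
                mean_speed=float(step[m].sum() / time_in),
                time_in_sector=float(time_in),
                n_spikes=n_sp,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "route_id",
            "firing_rate",
            "mean_x",
            "mean_y",
            "mean_speed",
            "time_in_sector",
            "n_spikes",
        ],
    )


def is_active_in_sector(stats_df: pd.DataFrame, threshold_hz: float = 1.0) -> bool:
    """Active iff any route's pooled rate (all spikes over all time on that
    route's traversals) strictly exceeds the threshold."""
    if len(stats_df) == 0:
        return False
    pooled = stats_df.groupby("route_id").apply(
        lambda g: g["n_spikes"].sum() / g["time_in_sector"].sum(),
        include_groups=False,
    )
    return bool((pooled > threshold_hz).any())


def _design(stats_df: pd.DataFrame, covariates, rank: bool):
    y = stats_df["firing_rate"].to_numpy(float)
    C = stats_df[list(covariates)].to_numpy(float)
    if rank:
        y = stats.rankdata(y)
        C = np.column_stack([stats.rankdata(c) for c in C.T])
    return y, C


def _drop_collinear(C: np.ndarray, names):
    """Drop covariate columns until [1 | C] has full column rank."""
    names = list(names)
    while C.shape[1] > 0:
        X = np.column_stack([np.ones(len(C)), C])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        # drop the last column involved in the deficiency
        warnings.warn(f"dropping collinear covariate {names[-1]!r}")
        C = C[:, :-1]
        names = names[:-1]
    return C, names


def _residualise(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), C])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _oneway_f(resid: np.ndarray, groups: np.ndarray):
    labels = np.unique(groups)
    n = len(resid)
    g = len(labels)
    grand = resid.mean()
    ssb = sum(len(resid[groups == lab]) * (resid[groups == lab].mean() - grand) ** 2 for lab in labels)
    ssw = sum(((resid[groups == lab] - resid[groups == lab].mean()) ** 2).sum() for lab in labels)
    if ssw <= 1e-12 * max(ssb, 1.0):
        if ssb <= 1e-12:
            return 0.0, 1.0, (g - 1, n - g)
        return np.inf, 0.0, (g - 1, n - g)
    f = (ssb / (g - 1)) / (ssw / (n - g))
    return float(f), float(stats.f.sf(f, g - 1, n - g)), (g - 1, n - g)


def _posthoc_marginal_means(resid: np.ndarray, groups: np.ndarray, method: str = "tukey"):
    """Six pairwise comparisons of group means of the residuals."""
    labels = np.unique(groups)
    n, g = len(resid), len(labels)
    means = {lab: resid[groups == lab].mean() for lab in labels}
    counts = {lab: int((groups == lab).sum()) for lab in labels}
    ssw = sum(((resid[groups == lab] - means[lab]) ** 2).sum() for lab in labels)
    dfw = n - g
    msw = ssw / dfw if dfw > 0 else np.nan
    rows = []
    n_pairs = g * (g - 1) // 2
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(msw * (1.0 / counts[a] + 1.0 / counts[b]))
        if not np.isfinite(se) or se == 0:
            p = 1.0 if diff == 0 else 0.0
        elif method == "tukey":
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(stats.studentized_range.sf(q, g, dfw))
        elif method == "sidak":
            tstat = abs(diff) / se
            p_raw = 2.0 * stats.t.sf(tstat, dfw)
            p = float(1.0 - (1.0 - min(p_raw, 1.0)) ** n_pairs)
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        rows.append(dict(route_a=int(a), route_b=int(b), estimate=float(diff), p=p))
    return pd.DataFrame(rows)


def _posthoc_mannwhitney(stats_df: pd.DataFrame, correction: str | None = None):
    rows = []
    for a, b in ROUTE_PAIRS:
        ra = stats_df.loc[stats_df["route_id"] == a, "firing_rate"]
        rb = stats_df.loc[stats_df["route_id"] == b, "firing_rate"]
        if len(ra) == 0 or len(rb) == 0:
            rows.append(dict(route_a=a, route_b=b, estimate=np.nan, p=np.nan))
            continue
        res = stats.mannwhitneyu(ra, rb, alternative="two-sided")
        p = float(res.pvalue)
        if correction == "sidak":
            p = float(1.0 - (1.0 - p) ** len(ROUTE_PAIRS))
        rows.append(dict(route_a=a, route_b=b, estimate=float(ra.mean() - rb.mean()), p=p))
    return pd.DataFrame(rows)


@dataclass
class DifferentialFiringResults:
    """Omnibus statistic, p-value and post-hoc table of one fitted cell-sector."""

    method: str
    statistic: float
    p_value: float
    df: tuple
    posthoc: pd.DataFrame | None
    n_trials: pd.Series
    alpha: float
    flags: tuple = ()

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def pattern(self, alpha: float | None = None) -> str:
        return classify_route_goal(self, alpha=alpha)

    def summary(self) -> str:
        lines = [
            f"Differential firing ({self.method})",
            "=" * 40,
            f"omnibus statistic : {self.statistic:.4f}",
            f"df                : {self.df}",
            f"p-value           : {self.p_value:.4g}",
            f"trials per route  : {{{', '.join(f'{int(k)}: {int(v)}' for k, v in self.n_trials.items())}}}",
            f"pattern           : {self.pattern()}",
        ]
        if self.flags:
            lines.append(f"flags             : {'; '.join(self.flags)}")
        if self.posthoc is not None:
            lines.append("post-hoc pairwise comparisons:")
            lines.append(self.posthoc.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class DifferentialFiring:
    """Model of route modulation of one cell's per-trial sector rates.

    Parameters
    ----------
    stats_df : DataFrame
        Output of :func:`sector_trial_stats` (one row per trial).
    alpha : float
        Omnibus and post-hoc significance level.
    covariates : sequence of str
        Trial covariates controlled for; defaults to mean x, mean y and
        mean running speed in the sector.
    min_trials_per_route : int
        Routes with fewer trials make the cell ineligible for scoring.
    """

    def __init__(
        self,
        stats_df: pd.DataFrame,
        alpha: float = 0.05,
        covariates=COVARIATES,
        min_trials_per_route: int = 5,
    ):
        self.stats = stats_df.reset_index(drop=True)
        self.alpha = alpha
        self.covariates = tuple(covariates)
        self.min_trials_per_route = min_trials_per_route

    @classmethod
    def from_spikes(cls, spike_times, traj, trials, sector, layout=None, **kwargs):
        include_errors = kwargs.pop("include_errors", False)
        stats_df = sector_trial_stats(
            spike_times, traj, trials, sector, layout, include_errors=include_errors
        )
        return cls(stats_df, **kwargs)

    @property
    def n_trials(self) -> pd.Series:
        return self.stats.groupby("route_id").size()

    @property
    def eligible(self) -> bool:
        """Enough routes and trials per route to score the cell."""
        n = self.n_trials
        return len(n) >= 2 and bool((n >= self.min_trials_per_route).all())

    def _check(self):
        n = self.n_trials
        if len(n) < 2 or (n < 2).any():
            raise ValueError("need at least 2 routes with at least 2 trials each")

    def fit(
        self,
        method: str = "ranked_ancova",
        k: int = 5000,
        seed=None,
        posthoc: str = "tukey",
    ) -> DifferentialFiringResults:
        self._check()
        if method == "ranked_ancova":
            return self._fit_ranked(posthoc)
        if method == "permutation_ancova":
            return self._fit_permutation(k, seed, posthoc)
        if method == "poisson_glm":
            return self._fit_glm(posthoc)
        raise ValueError(f"unknown method {method!r}")

    # -- method 1: rank-transform ANCOVA ---------------------------------
    def _fit_ranked(self, posthoc: str) -> DifferentialFiringResults:
        y, C = _design(self.stats, self.covariates, rank=True)
        groups = self.stats["route_id"].to_numpy().astype(int)
        flags = []
        if np.ptp(y) == 0:
            return DifferentialFiringResults(
                "ranked_ancova", 0.0, 1.0, (len(np.unique(groups)) - 1, len(y)),
                None, self.n_trials, self.alpha, ("constant firing rate",),
            )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            C, kept = _drop_collinear(C, self.covariates)
            flags += [str(w.message) for w in caught]
        resid = _residualise(y, C)
        f, p, dfs = _oneway_f(resid, groups)
        table = _posthoc_marginal_means(resid, groups, posthoc) if p < self.alpha else None
        return DifferentialFiringResults(
            "ranked_ancova", f, p, dfs, table, self.n_trials, self.alpha, tuple(flags)
        )

    # -- method 2: permutation ANCOVA F ----------------------------------
    def _fit_permutation(self, k: int, seed, posthoc: str) -> DifferentialFiringResults:
        if k < 100:
            warnings.warn("fewer than 100 shuffles gives a very coarse p-value")
        y, C = _design(self.stats, self.covariates, rank=False)
        groups = self.stats["route_id"].to_numpy().astype(int)
        flags = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            C, _ = _drop_collinear(C, self.covariates)
            flags += [str(w.message) for w in caught]
        labels = np.unique(groups)
        dummies = np.column_stack([(groups == lab).astype(float) for lab in labels[1:]])
        Xr = np.column_stack([np.ones(len(y)), C])
        Xf = np.column_stack([Xr, dummies])
        Qr, _ = np.linalg.qr(Xr)
        Qf, _ = np.linalg.qr(Xf)
        q = dummies.shape[1]
        dfe = len(y) - Xf.shape[1]

        def partial_f(Y):
            tot = np.sum(Y * Y, axis=0)
            rss_f = tot - np.sum((Qf.T @ Y) ** 2, axis=0)
            rss_r = tot - np.sum((Qr.T @ Y) ** 2, axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                return ((rss_r - rss_f) / q) / (rss_f / dfe)

        f_obs = float(partial_f(y[:, None])[0])
        rng = np.random.default_rng(seed)
        Y = rng.permuted(np.tile(y[:, None], (1, k)), axis=0)
        f_shuff = partial_f(Y)
        p = float(np.sum(f_shuff >= f_obs) / k)
        table = None
        if p < self.alpha:
            resid = _residualise(y, C)
            table = _posthoc_marginal_means(resid, groups, posthoc)
        return DifferentialFiringResults(
            "permutation_ancova", f_obs, p, (q, dfe), table, self.n_trials,
            self.alpha, tuple(flags) + (f"k={k}",),
        )

    # -- method 3: Poisson GLM --------------------------------------------
    def _fit_glm(self, posthoc: str, use_counts: bool = True) -> DifferentialFiringResults:
        import statsmodels.api as sm

        y, C = _design(self.stats, self.covariates, rank=False)
        groups = self.stats["route_id"].to_numpy().astype(int)
        flags = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            C, _ = _drop_collinear(C, self.covariates)
            flags += [str(w.message) for w in caught]
        labels = np.unique(groups)
        dummies = np.column_stack([(groups == lab).astype(float) for lab in labels[1:]])
        Xr = np.column_stack([np.ones(len(y)), C])
        Xf = np.column_stack([Xr, dummies])
        if use_counts and {"n_spikes", "time_in_sector"} <= set(self.stats.columns):
            dv = self.stats["n_spikes"].to_numpy(float)
            offset = np.log(self.stats["time_in_sector"].to_numpy(float))
        else:
            dv = y
            offset = None
            flags.append("raw-rate Poisson fit (no spike counts available)")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_f = sm.GLM(dv, Xf, family=sm.families.Poisson(), offset=offset).fit()
                fit_r = sm.GLM(dv, Xr, family=sm.families.Poisson(), offset=offset).fit()
            lr = 2.0 * (fit_f.llf - fit_r.llf)
            dfq = Xf.shape[1] - Xr.shape[1]
            p = float(stats.chi2.sf(lr, dfq))
        except Exception as e:  # non-convergence or separation
            return DifferentialFiringResults(
                "poisson_glm", np.nan, np.nan, (np.nan, np.nan), None,
                self.n_trials, self.alpha, tuple(flags) + (f"fit failed: {e}",),
            )
        table = _posthoc_mannwhitney(self.stats) if p < self.alpha else None
        return DifferentialFiringResults(
            "poisson_glm", float(lr), p, (dfq, len(y)), table, self.n_trials,
            self.alpha, tuple(flags),
        )


def classify_route_goal(result: DifferentialFiringResults, alpha: float | None = None) -> str:
    """Assign a route-specific / goal-dependent / unclassified label.

    route_specific_k: route k's rate differs (p < alpha) from each of the
    other three routes pairwise.  goal_dependent: routes 2 and 3 each differ
    from routes 1 and 4 (all four cross pairs significant) while the 2-3
    pair is not.  Anything else, or a missing post-hoc table, is
    unclassified.
    """
    if alpha is None:
        alpha = result.alpha
    table = result.posthoc
    if table is None or len(table) < 6 or table["p"].isna().any():
        return "unclassified"
    sig = {
        frozenset((int(r.route_a), int(r.route_b))): bool(r.p < alpha)
        for r in table.itertuples()
    }
    est = {
        frozenset((int(r.route_a), int(r.route_b))): float(r.estimate)
        for r in table.itertuples()
    }
    candidates = [
        k for k in (1, 2, 3, 4)
        if all(sig[frozenset((k, o))] for o in (1, 2, 3, 4) if o != k)
    ]
    if candidates:
        if len(candidates) == 1:
            return f"route_specific_{candidates[0]}"
        # more than one route differs from all others; take the one with the
        # largest mean pairwise separation (deterministic tie-break)
        sep = {
            k: np.mean([abs(est[frozenset((k, o))]) for o in (1, 2, 3, 4) if o != k])
            for k in candidates
        }
        return f"route_specific_{max(sep, key=sep.get)}"
    cross = [frozenset(p) for p in ((2, 1), (2, 4), (3, 1), (3, 4))]
    if all(sig[p] for p in cross) and not sig[frozenset((2, 3))]:
        return "goal_dependent"
    return "unclassified"


def population_pattern_tests(pattern_counts: dict) -> dict:
    """Chi-square goodness-of-fit tests on the population pattern counts.

    (a) the five pattern categories (route-specific 1-4 and goal-dependent)
    against a uniform expectation; (b) centre-preferring patterns (routes 2,
    3 and goal-dependent) against outer ones (routes 1 and 4) vs 50/50.
    """
    n = [int(pattern_counts.get(f"route_specific_{k}", 0)) for k in (1, 2, 3, 4)]
    n_goal = int(pattern_counts.get("goal_dependent", 0))
    obs5 = np.array(n + [n_goal], float)
    if obs5.sum() == 0:
        raise ValueError("no classified cells")
    chi5 = stats.chisquare(obs5)
    obs2 = np.array([n[1] + n[2] + n_goal, n[0] + n[3]], float)
    chi2c = stats.chisquare(obs2)
    return {
        "five_category": dict(
            statistic=float(chi5.statistic), p=float(chi5.pvalue), df=4,
            observed=obs5.tolist(), n=int(obs5.sum()),
        ),
        "centre_vs_outer": dict(
            statistic=float(chi2c.statistic), p=float(chi2c.pvalue), df=1,
            observed=obs2.tolist(), n=int(obs2.sum()),
        ),
    }
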