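"""Spike-cluster quality metrics and place-cell classification.

Isolation distance is the squared Mahalanobis distance (w.r.t. the cluster's
own feature covariance) of the n_c-th closest non-cluster spike to the
cluster centre; L is the summed chi-square upper-tail mass of non-cluster
distances and L_ratio = L / n_c.  A unit passes the place-cell screen when
its waveform width, mean rate and spatial information all clear strict
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import iterative_grubbs

__all__ = [
    "ClusterFeatureSet",
    "QualityMetrics",
    "PlaceCellCriteria",
    "spike_energy",
    "mahalanobis_sq",
    "isolation_distance",
    "l_ratio",
    "signal_to_noise",
    "classify_place_cell",
    "quality_metrics",
    "quality_effect_association",
]


@dataclass
class ClusterFeatureSet:
    """Feature vectors of one cluster and of all other (non-cluster) spikes."""

    cluster_points: np.ndarray  # (n_c, d)
    non_cluster_points: np.ndarray  # (m, d)

    def __post_init__(self):
        self.cluster_points = np.atleast_2d(np.asarray(self.cluster_points, float))
        self.non_cluster_points = np.atleast_2d(np.asarray(self.non_cluster_points, float))
        if self.cluster_points.shape[1] != self.non_cluster_points.shape[1]:
            raise ValueError("cluster and non-cluster feature dimensions differ")

    @property
    def n_c(self) -> int:
        return len(self.cluster_points)

    @property
    def dim(self) -> int:
        return self.cluster_points.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.cluster_points.mean(axis=0)

    @property
    def cov(self) -> np.ndarray:
        return np.cov(self.cluster_points, rowvar=False)


@dataclass(frozen=True)
class QualityMetrics:
    isolation_distance: float  # NaN when undefined (m < n_c or singular cov)
    l_ratio: float
    snr: float
    peak_amplitude: float
    n_c: int
    flags: tuple = ()


@dataclass(frozen=True)
class PlaceCellCriteria:
    min_width_us: float = 250.0
    rate_low_hz: float = 0.1
    rate_high_hz: float = 5.0
    min_info_bits: float = 0.5

    def __post_init__(self):
        if self.rate_low_hz >= self.rate_high_hz:
            raise ValueError("rate_low must be below rate_high")


def spike_energy(waveform) -> float:
    """Signal energy: sum of squared sample moduli."""
    w = np.asarray(waveform)
    if w.size == 0:
        raise ValueError("empty waveform")
    return float(np.sum(np.abs(w) ** 2))


def mahalanobis_sq(fs: ClusterFeatureSet) -> np.ndarray:
    """Squared Mahalanobis distances of non-cluster spikes to the cluster
    centre, under the cluster's sample covariance."""
    cov = fs.cov
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("cluster feature covariance is singular") from e
    d = fs.non_cluster_points - fs.mean
    return np.einsum("ij,jk,ik->i", d, inv, d)


def isolation_distance(fs: ClusterFeatureSet) -> float:
    """n_c-th smallest non-cluster squared Mahalanobis distance; higher is
    better isolated.  NaN when fewer non-cluster spikes than n_c."""
    if len(fs.non_cluster_points) < fs.n_c:
        return float("nan")
    d2 = np.sort(mahalanobis_sq(fs))
    return float(d2[fs.n_c - 1])


def l_ratio(fs: ClusterFeatureSet, df: int | None = None):
    """(L, L_ratio): summed chi-square survival mass of non-cluster
    distances, and that sum per cluster spike.  ``df`` defaults to the
    feature dimension (8 for four-tetrode-channel feature pairs)."""
    if df is None:
        df = fs.dim
    d2 = mahalanobis_sq(fs)
    L = float(np.sum(stats.chi2.sf(d2, df)))
    return L, L / fs.n_c


def signal_to_noise(mean_signal_amplitude: float, mean_noise_amplitude: float) -> float:
    """S/N across a common impedance; algebraically (mu_s / mu_n)^2."""
    if mean_noise_amplitude <= 0:
        raise ValueError("mean noise amplitude must be positive")
    return float((mean_signal_amplitude / mean_noise_amplitude) ** 2)


def quality_metrics(
    fs: ClusterFeatureSet,
    mean_signal_amplitude: float,
    mean_noise_amplitude: float,
    peak_amplitude: float | None = None,
    df: int | None = None,
) -> QualityMetrics:
    flags = []
    iso = isolation_distance(fs)
    if np.isnan(iso):
        flags.append("isolation distance undefined: fewer non-cluster spikes than n_c")
    _, lr = l_ratio(fs, df)
    snr = signal_to_noise(mean_signal_amplitude, mean_noise_amplitude)
    return QualityMetrics(
        isolation_distance=iso,
        l_ratio=lr,
        snr=snr,
        peak_amplitude=float(peak_amplitude if peak_amplitude is not None else mean_signal_amplitude),
        n_c=fs.n_c,
        flags=tuple(flags),
    )


def classify_place_cell(
    width_us: float,
    mean_rate_hz: float,
    info_bits: float,
    crit: PlaceCellCriteria = PlaceCellCriteria(),
):
    """Accept/reject a unit as a place cell; all thresholds are strict.

    Returns (accepted, reasons) where reasons lists every failed criterion.
    """
    if min(width_us, mean_rate_hz, info_bits) < 0:
        raise ValueError("width, rate and information must be nonnegative")
    reasons = []
    if not width_us > crit.min_width_us:
        reasons.append("width")
    if not (crit.rate_low_hz < mean_rate_hz < crit.rate_high_hz):
        reasons.append("rate")
    if not info_bits > crit.min_info_bits:
        reasons.append("information")
    return (not reasons), reasons


def quality_effect_association(
    metrics: pd.DataFrame,
    f_statistics: pd.DataFrame,
    alpha: float = 0.05,
    min_points: int = 10,
) -> pd.DataFrame:
    """Association between cluster quality and differential-firing strength.

    ``metrics`` has one row per cell (columns = metric names, index = cell
    id); ``f_statistics`` has columns ``cell_id``, ``F`` and a boolean
    ``differential`` flag, one row per assessed cell-sector.  For each
    metric: a two-sample Kolmogorov-Smirnov comparison of differential vs
    non-differential cells, and a Spearman correlation against the
    F-statistics after iterative Grubbs outlier removal on both variables.
    """
    rows = []
    per_cell_diff = f_statistics.groupby("cell_id")["differential"].any()
    for col in metrics.columns:
        vals = metrics[col]
        a = vals[per_cell_diff.reindex(vals.index, fill_value=False)].dropna()
        b = vals[~per_cell_diff.reindex(vals.index, fill_value=True)].dropna()
        if len(a) and len(b):
            ks = stats.ks_2samp(a, b)
            ks_d, ks_p = float(ks.statistic), float(ks.pvalue)
        else:
            ks_d, ks_p = np.nan, np.nan

        paired = f_statistics.join(vals.rename("metric"), on="cell_id").dropna(
            subset=["metric", "F"]
        )
        if len(paired) < min_points:
            rows.append(
                dict(metric=col, ks_d=ks_d, ks_p=ks_p, rho=np.nan, rho_p=np.nan,
                     n_pairs=len(paired), flag="too few paired observations")
            )
            continue
        keep = iterative_grubbs(paired["metric"].to_numpy(), alpha) & iterative_grubbs(
            paired["F"].to_numpy(), alpha
        )
        pruned = paired[keep]
        flag = ""
        if len(pruned) < min_points:
            flag = "too few points after outlier pruning"
            rho, rho_p = np.nan, np.nan
        else:
            rho, rho_p = stats.spearmanr(pruned["metric"], pruned["F"])
        rows.append(
            dict(metric=col, ks_d=ks_d, ks_p=ks_p, rho=float(rho) if rho == rho else np.nan,
                 rho_p=float(rho_p) if rho_p == rho_p else np.nan,
                 n_pairs=int(keep.sum()), flag=flag)
        )
    return pd.DataFrame(rows).set_index("metric")
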