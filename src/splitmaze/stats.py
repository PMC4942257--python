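"""Small statistical primitives shared across analyses.

Shuffle-null p-values are read off an Epanechnikov-kernel smoothed
cumulative distribution of the shuffle sample; outlier pruning before the
quality/effect correlations uses an iterative two-sided Grubbs test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "epanechnikov_bandwidth",
    "smoothed_cdf",
    "shuffle_pvalue",
    "grubbs_mask",
    "iterative_grubbs",
]


def epanechnikov_bandwidth(sample) -> float:
    """Silverman-style plug-in bandwidth for the Epanechnikov kernel,
    h = 2.345 * sigma * n^(-1/5) with a robust sigma estimate."""
    x = np.asarray(sample, float)
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.349 if n > 1 else 0.0
    sigma = min(s for s in (sd, iqr) if s > 0) if max(sd, iqr) > 0 else 0.0
    return 2.345 * sigma * n ** (-0.2) if sigma > 0 else 0.0


def smoothed_cdf(x, sample, bandwidth: float | None = None):
    """Epanechnikov-kernel smoothed CDF of ``sample`` evaluated at ``x``.

    The kernel K(u) = 0.75 (1 - u^2) on [-1, 1] has the closed-form integral
    0.5 + 0.75 u - 0.25 u^3, so the smoothed CDF is an average of these
    terms.  A zero bandwidth (degenerate sample) falls back to the empirical
    step CDF.
    """
    x = np.atleast_1d(np.asarray(x, float))
    s = np.asarray(sample, float)
    if bandwidth is None:
        bandwidth = epanechnikov_bandwidth(s)
    if bandwidth <= 0:
        out = np.mean(s[None, :] <= x[:, None], axis=1)
    else:
        u = np.clip((x[:, None] - s[None, :]) / bandwidth, -1.0, 1.0)
        out = np.mean(0.5 + 0.75 * u - 0.25 * u**3, axis=1)
    return out if out.size > 1 else float(out[0])


def shuffle_pvalue(observed: float, shuffles, bandwidth: float | None = None) -> float:
    """Upper-tail probability of ``observed`` under the shuffle distribution,
    1 - F_smooth(observed), clipped to [0, 1]."""
    return float(np.clip(1.0 - smoothed_cdf(observed, shuffles, bandwidth), 0.0, 1.0))


def grubbs_mask(x, alpha: float = 0.05):
    """One two-sided Grubbs test step: index of the rejected point or None."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 3:
        return None
    s = x.std(ddof=1)
    if s == 0:
        return None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / s
    tcrit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    gcrit = (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))
    return i if g > gcrit else None


def iterative_grubbs(x, alpha: float = 0.05):
    """Repeat single-outlier two-sided Grubbs removal until no rejection.

    Returns a boolean keep-mask over the input.
    """
    x = np.asarray(x, float)
    keep = np.ones(len(x), dtype=bool)
    while True:
        idx = np.flatnonzero(keep)
        j = grubbs_mask(x[idx], alpha)
        if j is None:
            return keep
        keep[idx[j]] = False
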