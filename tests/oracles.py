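"""Independent brute-force implementations used as oracles in the tests.

These deliberately avoid the package's vectorised code paths: explicit
double loops, normal-equations regression and textbook ANOVA sums.
"""

import numpy as np
from scipy import stats as sps


def brute_force_rate_map(spike_pos, path_xy, dt, centres, h):
    """Double-loop kernel rate estimate at each bin centre."""
    rates = []
    for cx, cy in centres:
        num = 0.0
        for sx, sy in spike_pos:
            num += np.exp(-0.5 * ((sx - cx) ** 2 + (sy - cy) ** 2) / h**2)
        den = 0.0
        for (px, py), d in zip(path_xy, dt):
            den += d * np.exp(-0.5 * ((px - cx) ** 2 + (py - cy) ** 2) / h**2)
        rates.append(num / den)
    return np.array(rates)


def brute_force_ranked_ancova(rate, covs, routes):
    """Rank DV and covariates, regress by normal equations, one-way ANOVA of
    residuals against route; returns (F, p)."""
    y = sps.rankdata(rate)
    C = np.column_stack([sps.rankdata(c) for c in np.asarray(covs, float).T])
    X = np.column_stack([np.ones(len(y)), C])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    groups = np.asarray(routes)
    labels = np.unique(groups)
    grand = resid.mean()
    ssb = 0.0
    ssw = 0.0
    for lab in labels:
        r = resid[groups == lab]
        ssb += len(r) * (r.mean() - grand) ** 2
        ssw += ((r - r.mean()) ** 2).sum()
    df1, df2 = len(labels) - 1, len(y) - len(labels)
    F = (ssb / df1) / (ssw / df2)
    return F, sps.f.sf(F, df1, df2)


def whiten(points):
    """Shift/rotate points so the sample mean is 0 and covariance identity."""
    x = np.asarray(points, float)
    x = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    L = np.linalg.cholesky(cov)
    return x @ np.linalg.inv(L).T


def exact_chisquare(observed, expected=None):
    """Pearson goodness of fit in exact rational arithmetic."""
    from fractions import Fraction

    obs = [Fraction(int(o)) for o in observed]
    n = sum(obs)
    if expected is None:
        expected = [Fraction(n, len(obs))] * len(obs)
    return float(sum((o - e) ** 2 / e for o, e in zip(obs, expected)))
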