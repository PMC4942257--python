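"""Win-stay session scoring: search errors, trial times, confusion pairs.

Within each block the first correct trial splits the block into a search
phase (the rat does not yet know the rewarded box) and a post-identification
phase; errors and mean trial durations are scored per phase, and
post-identification errors are grouped into the six unordered pairs of
{chosen route, rewarded route} ("confusion pairs" - taking Route 2 when 3
was rewarded and taking 3 when 2 was rewarded reflect the same confusion).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["score_blocks", "confusion_pairs"]

PAIRS = tuple(combinations((1, 2, 3, 4), 2))


def score_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-block error counts and mean trial durations, split at the first
    correct trial.  Blocks with no correct trial get NaN post-phase fields
    and a flag."""
    rows = []
    for block, g in trials.groupby("block"):
        g = g.sort_values("trial_id")
        correct = g["correct"].to_numpy()
        dur = g["duration"].to_numpy()
        if not correct.any():
            rows.append(
                dict(
                    block_id=block,
                    rewarded_route=int(g["rewarded_route"].iloc[0]),
                    errors_pre=int((~correct).sum()),
                    errors_post=np.nan,
                    n_correct=0,
                    mean_time_pre=float(dur.mean()),
                    mean_time_post=np.nan,
                    flag="no correct trial",
                )
            )
            continue
        first = int(np.argmax(correct))
        pre, post = dur[:first], dur[first:]
        rows.append(
            dict(
                block_id=block,
                rewarded_route=int(g["rewarded_route"].iloc[0]),
                errors_pre=int((~correct[:first]).sum()),
                errors_post=int((~correct[first:]).sum()),
                n_correct=int(correct.sum()),
                mean_time_pre=float(pre.mean()) if len(pre) else np.nan,
                mean_time_post=float(post.mean()),
                flag="",
            )
        )
    return pd.DataFrame(rows)


def confusion_pairs(trials: pd.DataFrame) -> pd.Series:
    """Counts of post-identification errors per unordered route pair.

    Only errors after the first correct trial of their block are counted;
    each goes to the pair {chosen route, rewarded route}.  The counts sum to
    the total post-identification errors.
    """
    counts = {p: 0 for p in PAIRS}
    for _, g in trials.groupby("block"):
        g = g.sort_values("trial_id")
        correct = g["correct"].to_numpy()
        if not correct.any():
            continue
        first = int(np.argmax(correct))
        for tr in g.iloc[first:].itertuples():
            if tr.correct:
                continue
            if int(tr.route_id) == int(tr.rewarded_route):
                raise ValueError("error trial with chosen route equal to rewarded route")
            counts[tuple(sorted((int(tr.route_id), int(tr.rewarded_route))))] += 1
    return pd.Series(counts, name="errors")
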