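"""Session bundle reading/writing: plain-text tracking, spikes and manifest.

A session directory holds ``position.tsv`` (columns t, x, y; seconds, cm),
one ``spikes_<cell>.tsv`` per cell (column t), ``trials.json`` (the trial
manifest) and optionally ``ground_truth.json`` (generator parameters for
recovery tests) and per-cell feature files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SessionBundle", "write_session", "read_session"]

_TRIAL_COLUMNS = [
    "trial_id",
    "block",
    "route_id",
    "rewarded_route",
    "correct",
    "is_search",
    "t_hold_start",
    "t_start",
    "t_goal",
    "t_end",
    "duration",
    "within_block_pos",
]


@dataclass
class SessionBundle:
    trajectory: pd.DataFrame
    trials: pd.DataFrame
    spikes: dict  # cell id -> spike-time array
    ground_truth: dict | None = None
    metadata: dict = field(default_factory=dict)
    dropped_spikes: dict = field(default_factory=dict)  # cell id -> count


def write_session(
    directory,
    trajectory: pd.DataFrame,
    trials: pd.DataFrame,
    spikes: dict,
    ground_truth: dict | None = None,
    metadata: dict | None = None,
) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    trajectory.to_csv(d / "position.tsv", sep="\t", index=False, float_format="%.6f")
    for cid, st in spikes.items():
        pd.DataFrame({"t": np.asarray(st, float)}).to_csv(
            d / f"spikes_{cid}.tsv", sep="\t", index=False, float_format="%.6f"
        )
    manifest = {
        "trials": trials[_TRIAL_COLUMNS].to_dict(orient="records"),
        "metadata": metadata or {},
        "cells": sorted(str(c) for c in spikes),
    }
    (d / "trials.json").write_text(json.dumps(manifest, indent=1, default=_json_default))
    if ground_truth is not None:
        (d / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=1, default=_json_default)
        )
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialise {type(o)}")


def read_session(directory) -> SessionBundle:
    """Read and validate a session directory.

    Timestamps must be strictly increasing (error reports the line number),
    trials must not overlap, and spikes outside the tracked time span are
    dropped with a warning and a per-cell count.
    """
    d = Path(directory)
    manifest_path = d / "trials.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing trial manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    trials = pd.DataFrame(manifest["trials"])

    traj = pd.read_csv(d / "position.tsv", sep="\t")
    t = traj["t"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ValueError(
            f"non-monotone timestamp in position.tsv at line {bad[0] + 3}"
        )  # +1 header, +1 next row, 1-based

    tr = trials.sort_values("t_hold_start")
    starts = tr["t_hold_start"].to_numpy()
    ends = tr["t_end"].to_numpy()
    if np.any(starts[1:] < ends[:-1] - 1e-9):
        raise ValueError("overlapping trials in manifest")

    spikes = {}
    dropped = {}
    for f in sorted(d.glob("spikes_*.tsv")):
        cid = f.stem.replace("spikes_", "", 1)
        st = pd.read_csv(f, sep="\t")["t"].to_numpy(float)
        inside = (st >= t[0]) & (st <= t[-1])
        n_drop = int((~inside).sum())
        if n_drop:
            warnings.warn(f"cell {cid}: dropped {n_drop} spike(s) outside trajectory span")
            dropped[cid] = n_drop
        spikes[cid] = st[inside]

    gt_path = d / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return SessionBundle(
        trajectory=traj,
        trials=trials,
        spikes=spikes,
        ground_truth=ground_truth,
        metadata=manifest.get("metadata", {}),
        dropped_spikes=dropped,
    )
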