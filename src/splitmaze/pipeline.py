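"""End-to-end session analysis: classification, rate maps, differential
firing, ensemble decoding, goal-box similarity and behavior scoring.

Each stage writes its own CSV into the report directory and contributes to
``summary.json``; a failing stage is recorded and later independent stages
still run.  A single session seed fans out to per-stage child seeds so any
stage can be re-run reproducibly in isolation.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import confusion_pairs, score_blocks
from .differential import (
    DifferentialFiring,
    is_active_in_sector,
    population_pattern_tests,
    sector_trial_stats,
)
from .ensemble import RouteDecoder, within_block_trend
from .goalbox import GoalBoxSimilarity, boxroute_vectors
from .io import SessionBundle, _json_default
from .maze import SCORED_SECTORS, build_maze_layout
from .ratemaps import (
    SmoothingParams,
    compute_occupancy,
    compute_rate_map,
    count_place_fields,
    sector_activity_profile,
    spatial_information,
)
from .unitquality import PlaceCellCriteria, classify_place_cell

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "method": "ranked_ancova",
    "n_shuffles_differential": 5000,
    "n_shuffles_ensemble": 10000,
    "n_shuffles_goalbox": 10000,
    "min_ensemble_cells": 6,
    "smoothing": {},
    "place_cell_criteria": {},
    "default_waveform_width_us": 300.0,
}


def _stage_seeds(seed, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(bundle: SessionBundle, out_dir, config: dict | None = None, seed: int = 0):
    """Run the full analysis on one session bundle; returns the summary dict."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = build_maze_layout()
    traj, trials = bundle.trajectory, bundle.trials
    seeds = _stage_seeds(seed, ["differential", "ensemble_start", "ensemble_stem", "goalbox"])
    summary = {"seed": seed, "n_cells_recorded": len(bundle.spikes), "errors": {}}

    def stage(name, fn):
        try:
            fn()
        except Exception as e:
            summary["errors"][name] = f"{type(e).__name__}: {e}"
            traceback.print_exc()

    place_cells = {}
    cell_rows = []

    def _classify():
        widths = (bundle.ground_truth or {}).get("waveform_width_us", {})
        crit = PlaceCellCriteria(**cfg["place_cell_criteria"])
        params = SmoothingParams(**cfg["smoothing"])
        occ = compute_occupancy(traj, params, layout)
        for cid, st in bundle.spikes.items():
            rm = compute_rate_map(st, traj, params, layout, occupancy=occ)
            info = spatial_information(rm)
            n_fields, _ = count_place_fields(rm)
            width = float(widths.get(str(cid), cfg["default_waveform_width_us"]))
            ok, reasons = classify_place_cell(width, rm.mean_rate, info, crit)
            cell_rows.append(
                dict(
                    cell_id=cid, mean_rate_hz=rm.mean_rate, peak_rate_hz=rm.peak_rate,
                    spatial_info_bits=info, n_fields=n_fields, width_us=width,
                    place_cell=ok, reject_reasons=";".join(reasons),
                )
            )
            if ok:
                place_cells[cid] = st
        pd.DataFrame(cell_rows).to_csv(out / "cells.csv", index=False)
        summary["n_place_cells"] = len(place_cells)

    stage("classification", _classify)
    cells = place_cells or bundle.spikes

    def _profile():
        profile, (r, p, df) = sector_activity_profile(cells, traj, layout)
        profile.to_csv(out / "sector_profile.csv", index=False)
        summary["sector_distance_correlation"] = {"r": r, "p": p, "df": df}
        summary["active_per_sector"] = dict(zip(profile["sector"], profile["n_active"].astype(int)))

    stage("sector_profile", _profile)

    def _differential():
        rows = []
        patterns = []
        for sector in SCORED_SECTORS:
            for cid, st in cells.items():
                stats_df = sector_trial_stats(st, traj, trials, sector, layout)
                if len(stats_df) == 0 or not is_active_in_sector(stats_df):
                    continue
                model = DifferentialFiring(stats_df, alpha=cfg["alpha"])
                if not model.eligible:
                    continue
                res = model.fit(
                    method=cfg["method"],
                    k=cfg["n_shuffles_differential"],
                    seed=seeds["differential"],
                )
                label = res.pattern()
                rows.append(
                    dict(
                        cell_id=cid, sector=sector, method=res.method,
                        statistic=res.statistic, p=res.p_value,
                        significant=res.significant, pattern=label,
                    )
                )
                if sector in ("start_box", "central_stem") and res.significant:
                    patterns.append((cid, label))
        df = pd.DataFrame(rows)
        df.to_csv(out / "differential.csv", index=False)
        summary["n_assessed"] = int(df["cell_id"].nunique()) if len(df) else 0
        summary["n_differential"] = (
            int(df.loc[df["significant"], "cell_id"].nunique()) if len(df) else 0
        )
        # one pattern per cell over start box / central stem; a classified
        # (non-'unclassified') label wins over unclassified
        per_cell = {}
        for cid, label in patterns:
            if cid not in per_cell or per_cell[cid] == "unclassified":
                per_cell[cid] = label
        counts = pd.Series(list(per_cell.values())).value_counts().to_dict()
        summary["pattern_counts"] = counts
        classified = {k: v for k, v in counts.items() if k != "unclassified"}
        if classified and sum(classified.values()) > 0:
            summary["pattern_tests"] = population_pattern_tests(classified)

    stage("differential", _differential)

    def _ensemble(sector, key):
        decoder = RouteDecoder.from_session(
            cells, traj, trials, sector, layout, min_cells=cfg["min_ensemble_cells"]
        )
        res = decoder.fit(n_shuffles=cfg["n_shuffles_ensemble"], seed=seeds[key])
        res.match_matrix.to_csv(out / f"decode_match_{sector}.csv")
        res.p_matrix.to_csv(out / f"decode_p_{sector}.csv")
        res.decode_log.to_csv(out / f"decode_log_{sector}.csv")
        summary[f"decode_{sector}"] = {
            "percent_correct": res.percent_correct,
            "diag_p": np.diag(res.p_matrix.to_numpy()).tolist(),
            "trend": within_block_trend(res.decode_log),
        }

    stage("ensemble_start_box", lambda: _ensemble("start_box", "ensemble_start"))
    stage("ensemble_central_stem", lambda: _ensemble("central_stem", "ensemble_stem"))

    def _goalbox():
        vectors = boxroute_vectors([(cells, traj, trials)], layout)
        res = GoalBoxSimilarity(vectors).fit(
            n_shuffles=cfg["n_shuffles_goalbox"], seed=seeds["goalbox"]
        )
        tab = pd.DataFrame({"rho": res.rho, "p": res.p})
        tab.index = [f"{a}|{b}" for a, b in tab.index]
        tab.to_csv(out / "goalbox.csv")
        summary["goalbox"] = {k: {"rho": res.rho[kk], "p": res.p[kk]}
                              for kk, k in zip(res.rho.index, tab.index)}

    stage("goalbox", _goalbox)

    def _behavior():
        blocks = score_blocks(trials)
        blocks.to_csv(out / "behavior_blocks.csv", index=False)
        pairs = confusion_pairs(trials)
        named = pairs.copy()
        named.index = [f"{a}-{b}" for a, b in pairs.index]
        named.to_csv(out / "confusion_pairs.csv")
        summary["behavior"] = {
            "mean_errors_pre": float(blocks["errors_pre"].mean()),
            "mean_time_pre_s": float(blocks["mean_time_pre"].mean(skipna=True)),
            "mean_time_post_s": float(blocks["mean_time_post"].mean(skipna=True)),
            "confusion_pairs": {f"{a}-{b}": int(v) for (a, b), v in pairs.items()},
        }

    stage("behavior", _behavior)

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))
    return summary
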