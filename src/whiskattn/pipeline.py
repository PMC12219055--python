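"""End-to-end orchestration: simulate -> behavior -> neural -> rf ->
decode -> report, with a manifest recording seeds and per-stage counts.

Every stochastic stage receives a seed derived from the master seed via
a counter-based scheme, so the manifest suffices to reproduce every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from whiskattn import __version__, behavior, decode, io, neural, rf
from whiskattn.grid import generate_whisker_grid
from whiskattn.simulate import (BehaviorGenConfig, NeuralGenConfig,
                                generate_neural_population, generate_session)
from whiskattn.stats import spawn_seeds

__all__ = ["default_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "behavior", "neural", "rf", "decode", "report")

log = logging.getLogger("whiskattn")


def default_config(seed: int = 0, out_dir: str = "whiskattn_run") -> dict:
    return {
        "seed": seed,
        "out_dir": out_dir,
        "stages": list(STAGES),
        "engagement": {"window": 50, "cutoff": 0.5},
        "history": {"mode": "consecutive", "reward_threshold_fraction": 0.0},
        "statistics": {"n_iterations": 2000, "alpha": 0.05, "fdr": True},
        "simulate": {"n_trials": 600, "n_cells": 40, "cell_class": "PYR"},
        "decoder": {"n_iterations": 5, "n_folds": 5,
                    "min_per_class": 5},
    }


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default))


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns the manifest dict.

    Tables and JSON reports land in ``config["out_dir"]``. A stage
    failure halts the run with the stage name in the raised error;
    partial outputs are retained.
    """
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    seeds = dict(zip(["simulate", "neural", "responsiveness", "decode"],
                     spawn_seeds(master_seed, 4)))
    stages = config.get("stages", list(STAGES))
    manifest = {"version": __version__, "seed": master_seed,
                "stage_seeds": seeds, "stages_completed": [], "counts": {}}

    stage = "simulate"
    try:
        grid = generate_whisker_grid()
        sim_cfg = config.get("simulate", {})
        if stage in stages:
            bcfg = BehaviorGenConfig(n_trials=int(sim_cfg.get("n_trials", 600)))
            session = generate_session(bcfg, grid, seed=seeds["simulate"])
            ncfg = NeuralGenConfig(
                n_cells=int(sim_cfg.get("n_cells", 40)),
                cell_class=str(sim_cfg.get("cell_class", "PYR")))
            ndata = generate_neural_population(ncfg, session,
                                               seed=seeds["neural"])
            io.write_session(session, out / "trials.tsv")
            io.write_cells(ndata.cells, out / "cells.tsv")
            io.write_responses(out / "responses.h5", ndata.evoked,
                               ndata.cells.cell_ids)
            io.write_truth_sidecar(out / "truth.json", session, ndata)
            manifest["counts"]["trials"] = len(session)
            manifest["counts"]["cells"] = len(ndata.cells)
            manifest["stages_completed"].append(stage)
        else:
            session = io.read_session(config["trial_table"], grid)
            ndata = None

        stage = "behavior"
        if stage in stages:
            eng = config.get("engagement", {})
            first, last = behavior.engagement_window(
                session, window=int(eng.get("window", 50)),
                cutoff=float(eng.get("cutoff", 0.5)))
            hist_cfg = config.get("history", {})
            labels = behavior.classify_trial_history(
                session, mode=hist_cfg.get("mode", "consecutive"),
                reward_threshold_fraction=float(
                    hist_cfg.get("reward_threshold_fraction", 0.0)))
            sdt = behavior.history_conditioned_sdt(
                session, labels, window=(first, last))
            rows = []
            for cat, entry in sdt["conditions"].items():
                m = entry["metrics"]
                rows.append({
                    "category": cat, "n_go": m.n_go, "n_nogo": m.n_nogo,
                    "hit_rate": round(m.hit_rate, 9),
                    "fa_rate": round(m.fa_rate, 9),
                    "d_prime": round(m.d_prime, 9),
                    "criterion": round(m.criterion, 9),
                    "delta_d": (round(entry["delta_d"], 9)
                                if entry["delta_d"] is not None else None),
                    "delta_c": (round(entry["delta_c"], 9)
                                if entry["delta_c"] is not None else None),
                })
            _dump({"engagement_window": [first, last], "conditions": rows},
                  out / "behavior.json")
            manifest["counts"]["engaged_trials"] = last - first + 1
            manifest["stages_completed"].append(stage)
        else:
            labels = behavior.classify_trial_history(session)
            first, last = session.trials[0].index, session.trials[-1].index

        stage = "neural"
        responsive = None
        if stage in stages and ndata is not None:
            stats_cfg = config.get("statistics", {})
            nogo_mask = np.array([t.kind == "NoGo" and not t.aborted
                                  for t in session.trials])
            resp_seeds = spawn_seeds(seeds["responsiveness"],
                                     len(ndata.cells))
            responsive = np.zeros(len(ndata.cells), dtype=bool)
            for c in range(len(ndata.cells)):
                go_by_w = {}
                for w in grid.whiskers:
                    mask = np.array([t.kind == "Go" and not t.aborted
                                     and t.whisker == w
                                     for t in session.trials])
                    if mask.sum() >= neural.MIN_TRIALS_PER_CONDITION:
                        go_by_w[w] = ndata.evoked[mask, c]
                res = neural.responsiveness_test(
                    go_by_w, ndata.evoked[nogo_mask, c],
                    n_iterations=int(stats_cfg.get("n_iterations", 2000)),
                    seed=resp_seeds[c],
                    alpha=float(stats_cfg.get("alpha", 0.05)))
                responsive[c] = res.responsive
            amis = neural.ami_per_cell(ndata.evoked, session, labels)
            ami_rows = [{
                "cell_id": cid,
                "ami_same_vs_nogo": a.ami_same_vs_nogo,
                "ami_diff_vs_nogo": a.ami_diff_vs_nogo,
                "ami_same_vs_diff": a.ami_same_vs_diff,
                "valid": a.valid,
                "responsive": bool(r),
            } for cid, a, r in zip(ndata.cells.cell_ids, amis, responsive)]
            profile = neural.somatotopic_profile(ndata.cells, ndata.evoked,
                                                 session, labels)
            _dump({"ami": ami_rows,
                   "n_responsive": int(responsive.sum()),
                   "somatotopic_profile": {
                       k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in profile.items()}},
                  out / "neural.json")
            manifest["counts"]["responsive_cells"] = int(responsive.sum())
            manifest["stages_completed"].append(stage)

        stage = "rf"
        if stage in stages and ndata is not None:
            res = rf.rf_shift_per_cell(ndata.evoked, session, labels,
                                       ndata.cells)
            shift_rows = [{"cell_id": cid, "shift": round(r.shift, 9),
                           "n_targets": r.n_targets_averaged}
                          for cid, r in res["shifts"].items()]
            _dump({"shifts": shift_rows,
                   "n_excluded": len(res["excluded"])},
                  out / "rf.json")
            manifest["counts"]["rf_cells"] = len(shift_rows)
            manifest["stages_completed"].append(stage)

        stage = "decode"
        if stage in stages and ndata is not None:
            dec_cfg = config.get("decoder", {})
            active = np.array([not t.aborted for t in session.trials])
            y = np.array([1 if t.kind == "Go" else 0
                          for t in session.trials])
            outcomes = np.array([t.outcome for t in session.trials])
            try:
                report = decode.evaluate_decoder(
                    ndata.evoked[active], y[active], outcomes[active],
                    session, labels,
                    responsive_mask=responsive,
                    seed=seeds["decode"],
                    n_iterations=int(dec_cfg.get("n_iterations", 5)),
                    n_folds=int(dec_cfg.get("n_folds", 5)),
                    min_per_class=int(dec_cfg.get("min_per_class", 5)))
            except ValueError as e:
                log.warning("decoder skipped: %s", e)
                report = {"skipped": str(e)}
            if "conditions" in report:
                report = {
                    "overall_accuracy": report["overall_accuracy"],
                    "shuffled_accuracy": report["shuffled_accuracy"],
                    "fbw": report["fbw"],
                    "conditions": [{
                        "filter": k[0], "history": k[1],
                        "fraction_stimulus_called":
                            round(v.fraction_stimulus_called, 9),
                        "n_trials": v.n_trials,
                    } for k, v in report["conditions"].items()],
                }
            _dump(report, out / "decoder.json")
            manifest["stages_completed"].append(stage)

        stage = "report"
        if stage in stages:
            cfg_text = json.dumps(config, sort_keys=True,
                                  default=_json_default)
            manifest["config_hash"] = hashlib.sha256(
                cfg_text.encode()).hexdigest()[:16]
            manifest["stages_completed"].append(stage)
            _dump(manifest, out / "manifest.json")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return manifest
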