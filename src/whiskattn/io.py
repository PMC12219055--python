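"""Disk formats: trial tables, cell tables, response containers, configs.

Trial and cell tables are tab-delimited text with fixed column sets;
response matrices live in HDF5 (datasets /evoked and optionally
/traces, window metadata as attributes) with a delimited fallback for
/evoked. Ground truth from the synthetic generator travels in a JSON
sidecar. Run configuration is TOML. Trial indices are 0-based on disk
and in memory.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from whiskattn.behavior import Session, Trial
from whiskattn.grid import WhiskerGrid, generate_whisker_grid
from whiskattn.simulate import CellTable

__all__ = [
    "TRIAL_COLUMNS",
    "CELL_COLUMNS",
    "write_session",
    "read_session",
    "write_cells",
    "read_cells",
    "write_responses",
    "read_responses",
    "read_config",
    "write_config",
    "ValidationError",
]

TRIAL_COLUMNS = ["trial_index", "onset_time_s", "kind", "whisker",
                 "amplitude_um", "outcome", "reward_ul",
                 "first_lick_latency_s", "aborted"]
CELL_COLUMNS = ["cell_id", "x_um", "y_um", "depth_um", "column",
                "cell_class", "layer"]


class ValidationError(ValueError):
    """A table violated the on-disk schema; message names the row."""


def write_session(session: Session, path) -> None:
    rows = []
    for t in session.trials:
        rows.append({
            "trial_index": t.index,
            "onset_time_s": t.onset_time,
            "kind": t.kind,
            "whisker": t.whisker if t.whisker is not None else "",
            "amplitude_um": t.amplitude,
            "outcome": t.outcome,
            "reward_ul": t.reward_volume,
            "first_lick_latency_s": (t.first_lick_latency
                                     if t.first_lick_latency is not None
                                     else ""),
            "aborted": int(t.aborted),
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def read_session(path, grid: WhiskerGrid | None = None,
                 **session_kwargs) -> Session:
    """Read a trial table; raises ValidationError naming the bad row."""
    df = pd.read_csv(path, sep="\t", dtype={"whisker": str},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    if grid is None:
        grid = generate_whisker_grid()
    trials = []
    prev_onset = -np.inf
    for i, row in df.iterrows():
        onset = float(row["onset_time_s"])
        if onset <= prev_onset:
            raise ValidationError(
                f"row {i}: onset time {onset} not strictly increasing")
        prev_onset = onset
        whisker = row["whisker"] or None
        lat = row["first_lick_latency_s"]
        lat = float(lat) if lat not in ("", None) else None
        try:
            trials.append(Trial(
                index=int(row["trial_index"]),
                onset_time=onset,
                kind=str(row["kind"]),
                whisker=whisker,
                amplitude=float(row["amplitude_um"]),
                outcome=str(row["outcome"]),
                reward_volume=float(row["reward_ul"]),
                first_lick_latency=lat,
                aborted=bool(int(row["aborted"])),
            ))
        except ValueError as e:
            raise ValidationError(f"row {i}: {e}") from e
        if whisker is not None and whisker not in grid.coordinates:
            raise ValidationError(f"row {i}: unknown whisker {whisker!r}")
    return Session(trials=trials, grid=grid, **session_kwargs)


def write_cells(cells: CellTable, path) -> None:
    df = pd.DataFrame({
        "cell_id": cells.cell_ids,
        "x_um": cells.xy_um[:, 0],
        "y_um": cells.xy_um[:, 1],
        "depth_um": cells.depth_um,
        "column": cells.column,
        "cell_class": cells.cell_class,
        "layer": cells.layer,
    }, columns=CELL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cells(path) -> CellTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    return CellTable(
        cell_ids=[str(c) for c in df["cell_id"]],
        xy_um=df[["x_um", "y_um"]].to_numpy(dtype=float),
        depth_um=df["depth_um"].to_numpy(dtype=float),
        column=[str(c) for c in df["column"]],
        cw=[str(c) for c in df["column"]],
        cell_class=[str(c) for c in df["cell_class"]],
        layer=[str(c) for c in df["layer"]],
    )


def write_responses(path, evoked: np.ndarray, cell_ids,
                    traces: np.ndarray | None = None,
                    frame_rate: float = 7.5, onset_frame: int = 8,
                    post_window: int = 7, baseline_window: int = 2) -> None:
    """HDF5 response container with window metadata as attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("evoked", data=np.asarray(evoked, dtype=float))
        d.attrs["cell_ids"] = [str(c) for c in cell_ids]
        f.attrs["frame_rate"] = frame_rate
        f.attrs["onset_frame"] = onset_frame
        f.attrs["post_window_frames"] = post_window
        f.attrs["baseline_window_frames"] = baseline_window
        if traces is not None:
            f.create_dataset("traces", data=np.asarray(traces, dtype=float))


def read_responses(path, cell_ids=None) -> dict:
    """Read a response container (HDF5, or delimited /evoked fallback).

    With ``cell_ids`` given, checks referential integrity against the
    container's cell list.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            out = {
                "evoked": f["evoked"][()],
                "cell_ids": [c.decode() if isinstance(c, bytes) else str(c)
                             for c in f["evoked"].attrs["cell_ids"]],
                "frame_rate": float(f.attrs["frame_rate"]),
                "onset_frame": int(f.attrs["onset_frame"]),
                "post_window_frames": int(f.attrs["post_window_frames"]),
                "baseline_window_frames": int(f.attrs["baseline_window_frames"]),
                "traces": f["traces"][()] if "traces" in f else None,
            }
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        out = {"evoked": df.to_numpy(dtype=float),
               "cell_ids": [str(c) for c in df.columns],
               "frame_rate": 7.5, "onset_frame": 8,
               "post_window_frames": 7, "baseline_window_frames": 2,
               "traces": None}
    if cell_ids is not None:
        unknown = [c for c in out["cell_ids"] if c not in set(cell_ids)]
        if unknown:
            raise ValidationError(
                f"response matrix references unknown cell_ids: {unknown[:5]}")
    return out


def write_truth_sidecar(path, session, neural=None) -> None:
    payload = {
        "effective_dprime": [None if np.isnan(v) else float(v)
                             for v in session.truth["effective_dprime"]],
        "criterion": [float(v) for v in session.truth["criterion"]],
        "seed": session.truth.get("seed"),
    }
    if neural is not None:
        payload["gain_mean_per_trial"] = neural.truth_gain.mean(
            axis=1).tolist()
    Path(path).write_text(json.dumps(payload))


def read_config(path) -> dict:
    with open(path, "rb") as f:
        return tomllib.load(f)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_config(config: dict, path) -> None:
    """Write a (possibly nested one level) dict as TOML."""
    lines = []
    tables = {k: v for k, v in config.items() if isinstance(v, dict)}
    scalars = {k: v for k, v in config.items() if not isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for name, table in tables.items():
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
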