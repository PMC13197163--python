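"""Readers, writers and configuration.

File dialects
-------------
Keypoint tables use the DLC-style layout: a three-level column header
(scorer / bodypart / coordinate with coordinates x, y, likelihood), one
row per frame, as CSV or HDF5.  Spike tables are tidy CSV with columns
(neuron_id, trial_id, t_s), times in seconds from trial start, sorted
within each trial.  Schedules are CSV with columns (index, velocity,
units, onset_s, duration_s) plus an optional axis column, with a JSON
mirror.  All angles are degrees, all times seconds, frame indices
0-based, stimulus intervals half-open [onset, onset + duration).
"""

from __future__ import annotations

import configparser
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import BODY_PARTS, KeypointTrack
from .stimuli import VelocitySchedule

__all__ = [
    "PipelineConfig",
    "read_keypoint_table",
    "write_keypoint_table",
    "read_spike_table",
    "write_spike_table",
    "read_schedule",
    "write_schedule",
    "write_tidy_results",
]

REQUIRED_PARTS = (
    "thorax_anterior",
    "thorax_posterior",
    "wing_tip_L",
    "wing_tip_R",
)


@dataclass
class PipelineConfig:
    """Protocol constants and QC options; defaults are the protocol values."""

    seed: int = 0
    # stimulus protocol
    pre_stim_s: float = 1.0
    step_duration_s: float = 2.0
    repetitions: int = 3
    refresh_hz: float = 165.0
    # spike analysis
    boxcar_width_s: float = 0.1
    rate_resolution_s: float = 2.5e-5
    tuning_skip_s: float = 0.1
    optic_flow_duration_s: float = 0.97
    # spontaneous windows (s)
    spont_rf_s: float = 0.8
    spont_optic_flow_s: float = 0.48
    spont_velocity_s: float = 2.0
    # receptive-field exclusion
    min_lms: float = 20.0
    min_positions: int = 5
    max_dispersion_deg: float = 30.0
    # kinematics QC
    likelihood_floor: float = 0.6
    qc_span_s: float = 0.5
    qc_threshold: float = 0.05
    qc_min_duration_s: float = 1.0
    flight_floor_deg: float = 40.0
    flight_min_duration_s: float = 0.5
    qc_relative: bool = True

    def save(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["pipeline"] = {
            f.name: repr(getattr(self, f.name)) for f in dataclasses.fields(self)
        }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in cp["pipeline"]:
                raw = cp["pipeline"][f.name]
                if f.type == "bool":
                    kwargs[f.name] = raw == "True"
                elif f.type == "int":
                    kwargs[f.name] = int(raw)
                else:
                    kwargs[f.name] = float(raw)
        return cls(**kwargs)


def read_keypoint_table(
    path,
    frame_rate: float = 100.0,
    likelihood_floor: float = 0.6,
    required_parts=REQUIRED_PARTS,
) -> KeypointTrack:
    """Read a DLC-dialect keypoint table (CSV or HDF5) into a track.

    The scorer level of the column header is dropped; frames must be
    uniformly indexed; missing required body parts raise an error naming
    them.  Low-likelihood points are masked downstream via the track's
    ``likelihood_floor``.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path)
    else:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if df.columns.nlevels == 3:
        df.columns = df.columns.droplevel(0)
    df.columns = pd.MultiIndex.from_tuples(
        [(p, c) for p, c in df.columns], names=["bodypart", "coordinate"]
    )
    parts = set(df.columns.get_level_values(0))
    missing = [p for p in required_parts if p not in parts]
    if missing:
        raise ValueError(f"keypoint table missing body parts: {missing}")
    idx = np.asarray(df.index, dtype=float)
    if idx.size > 1:
        steps = np.diff(idx)
        if not np.allclose(steps, steps[0]):
            raise ValueError("frame index must be uniformly spaced")
    df = df.astype(float).reset_index(drop=True)
    return KeypointTrack(data=df, frame_rate=frame_rate,
                         likelihood_floor=likelihood_floor)


def write_keypoint_table(track: KeypointTrack, path, scorer: str = "ofsdn") -> None:
    """Write a track back to DLC-dialect CSV or HDF5."""
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, p, c) for p, c in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="keypoints", mode="w")
    else:
        df.to_csv(path)


def read_spike_table(path) -> pd.DataFrame:
    """Tidy spike table (neuron_id, trial_id, t_s); validates sortedness."""
    df = pd.read_csv(path)
    missing = {"neuron_id", "trial_id", "t_s"} - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    for (_, _), sub in df.groupby(["neuron_id", "trial_id"]):
        t = sub["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            first_bad = sub.index[np.flatnonzero(np.diff(t) < 0)[0] + 1]
            raise ValueError(f"spike times not sorted (row {first_bad})")
    return df


def write_spike_table(df: pd.DataFrame, path) -> None:
    df.sort_values(["neuron_id", "trial_id", "t_s"]).to_csv(path, index=False)


def write_schedule(schedule: VelocitySchedule, path) -> None:
    """Write a schedule as CSV, or as its JSON mirror for .json paths."""
    rows = [
        {"index": i, "velocity": v, "units": _units(schedule.axis),
         "onset_s": t0, "duration_s": d, "axis": schedule.axis}
        for i, v, t0, d in schedule.steps()
    ]
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "axis": schedule.axis,
            "pre_stim_s": schedule.pre_stim,
            "seed": schedule.seed,
            "entries": rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def _units(axis: str) -> str:
    return "deg/s" if axis in ("roll", "pitch", "yaw") else "m/s"


def read_schedule(path) -> VelocitySchedule:
    """Read a schedule from CSV or JSON written by :func:`write_schedule`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        entries = tuple(
            (float(e["velocity"]), float(e["duration_s"])) for e in payload["entries"]
        )
        return VelocitySchedule(
            entries=entries,
            axis=payload.get("axis", "roll"),
            pre_stim=float(payload["pre_stim_s"]),
            seed=payload.get("seed"),
        )
    df = pd.read_csv(path)
    missing = {"index", "velocity", "onset_s", "duration_s"} - set(df.columns)
    if missing:
        raise ValueError(f"schedule missing columns: {sorted(missing)}")
    df = df.sort_values("index")
    entries = tuple(zip(df["velocity"].astype(float), df["duration_s"].astype(float)))
    pre = float(df["onset_s"].iloc[0])
    axis = str(df["axis"].iloc[0]) if "axis" in df.columns else (
        "roll" if str(df.get("units", pd.Series(["m/s"])).iloc[0]) == "deg/s" else "sideslip"
    )
    expected = pre + np.concatenate([[0.0], np.cumsum(df["duration_s"].to_numpy()[:-1])])
    if not np.allclose(df["onset_s"].to_numpy(dtype=float), expected):
        raise ValueError("schedule onsets are not contiguous")
    return VelocitySchedule(entries=entries, axis=axis, pre_stim=pre)


def write_tidy_results(df: pd.DataFrame, path) -> None:
    """Write a results table sorted deterministically by all its columns."""
    out = df.sort_values(list(df.columns)).reset_index(drop=True)
    out.to_csv(path, index=False)
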