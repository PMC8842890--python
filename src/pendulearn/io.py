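"""File formats: per-block CSV and cohort-scale HDF5.

Block CSV: header ``t,y,z[,y_dot,z_dot,y_ddot,z_ddot][,theta,theta_dot]
[,tau_shoulder,tau_elbow]``, SI units, '.' decimal, UTF-8.  Missing
derivative columns are reconstructed by central differences on read.

Cohort HDF5 layout::

    /participants/<id>/blocks/<n>/pivot      (n, 7) t,y,z,y_dot,z_dot,y_ddot,z_ddot
    /participants/<id>/blocks/<n>/states     (n, 2) theta, theta_dot
    /participants/<id>/blocks/<n>/torques    (n, 2) shoulder, elbow
    /metrics/<column>                         per-block metrics table
    /questionnaires/<column>                  item-level responses

The metrics/questionnaire tables can also be exported to CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .cohort import CohortDataset, ParticipantProfile
from .exceptions import FormatError
from .pendulum import PendulumTrace, PivotTrajectory
from .records import BlockRecording, Modality

__all__ = [
    "BlockData",
    "read_block_csv",
    "write_block_csv",
    "save_cohort",
    "load_cohort",
]

_PIVOT_COLS = ("t", "y", "z", "y_dot", "z_dot", "y_ddot", "z_ddot")
_STATE_COLS = ("theta", "theta_dot")
_TORQUE_COLS = ("tau_shoulder", "tau_elbow")


@dataclass
class BlockData:
    """Contents of one block file."""

    pivot: PivotTrajectory
    states: Optional[PendulumTrace] = None
    torques: Optional[np.ndarray] = None


def read_block_csv(path) -> BlockData:
    """Read a block trajectory CSV, validating layout and time axis.

    Velocities and accelerations are reconstructed by second-order central
    differences when the file carries positions only.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(frame.columns)
    if cols[:3] != ["t", "y", "z"]:
        raise FormatError(
            f"{path}: header must start with 't,y,z' (got {cols[:3]})")
    unknown = [c for c in cols
               if c not in _PIVOT_COLS + _STATE_COLS + _TORQUE_COLS]
    if unknown:
        raise FormatError(f"{path}: unknown columns {unknown}")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise FormatError(f"{path}: missing value near line {row}")
    t = frame["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: non-monotone time column near line {int(bad[0]) + 3}")
    if all(c in cols for c in _PIVOT_COLS):
        pivot = PivotTrajectory(*(frame[c].to_numpy(dtype=float)
                                  for c in _PIVOT_COLS))
    else:
        pivot = PivotTrajectory.from_positions(
            t, frame["y"].to_numpy(dtype=float),
            frame["z"].to_numpy(dtype=float))
    states = None
    if all(c in cols for c in _STATE_COLS):
        states = PendulumTrace(t, frame["theta"].to_numpy(dtype=float),
                               frame["theta_dot"].to_numpy(dtype=float))
    torques = None
    if all(c in cols for c in _TORQUE_COLS):
        torques = frame[list(_TORQUE_COLS)].to_numpy(dtype=float)
    return BlockData(pivot=pivot, states=states, torques=torques)


def write_block_csv(path, pivot: PivotTrajectory,
                    states: Optional[PendulumTrace] = None,
                    torques: Optional[np.ndarray] = None) -> None:
    """Write a block to CSV with full derivative columns."""
    data = {c: getattr(pivot, c) for c in _PIVOT_COLS}
    if states is not None:
        data["theta"] = states.theta
        data["theta_dot"] = states.theta_dot
    if torques is not None:
        torques = np.asarray(torques, dtype=float)
        data["tau_shoulder"] = torques[:, 0]
        data["tau_elbow"] = torques[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def _write_table(group: h5py.Group, frame: pd.DataFrame) -> None:
    str_dtype = h5py.string_dtype(encoding="utf-8")
    group.attrs["columns"] = json.dumps(list(frame.columns))
    for col in frame.columns:
        values = frame[col]
        if values.dtype == object or str(values.dtype).startswith("str"):
            group.create_dataset(col, data=values.astype(str).to_numpy(),
                                 dtype=str_dtype)
        elif values.dtype == bool:
            group.create_dataset(col, data=values.to_numpy(dtype=np.int8))
            group[col].attrs["bool"] = True
        else:
            # object columns with None become float NaN
            group.create_dataset(
                col, data=pd.to_numeric(values).to_numpy(dtype=float))


def _read_table(group: h5py.Group) -> pd.DataFrame:
    columns = json.loads(group.attrs["columns"])
    data = {}
    for col in columns:
        ds = group[col]
        values = ds[()]
        if ds.dtype.kind in ("O", "S"):
            values = np.array([v.decode() if isinstance(v, bytes) else v
                               for v in values], dtype=object)
        elif ds.attrs.get("bool", False):
            values = values.astype(bool)
        data[col] = values
    return pd.DataFrame(data, columns=columns)


def save_cohort(cohort: CohortDataset, path) -> None:
    """Write a cohort dataset (and any recordings it carries) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["config"] = json.dumps(cohort.config)
        _write_table(f.create_group("metrics"), cohort.metrics)
        _write_table(f.create_group("questionnaires"), cohort.questionnaires)
        parts = f.create_group("participants")
        for profile in cohort.profiles:
            g = parts.create_group(profile.participant_id)
            for key, val in vars(profile).items():
                g.attrs[key] = val
            if cohort.recordings and profile.participant_id in cohort.recordings:
                blocks = g.create_group("blocks")
                recs = cohort.recordings[profile.participant_id]
                for idx, rec in recs.items():
                    b = blocks.create_group(str(idx))
                    b.attrs["phase_label"] = rec.phase_label
                    b.attrs["rod_length"] = rec.rod_length
                    b.attrs["hr"] = rec.modality.hr
                    b.attrs["ws"] = rec.modality.ws
                    if rec.score is not None:
                        b.attrs["score"] = rec.score
                    if rec.training_position is not None:
                        b.attrs["training_position"] = rec.training_position
                    b.create_dataset("pivot", data=np.column_stack(
                        [getattr(rec.pivot, c) for c in _PIVOT_COLS]))
                    b.create_dataset("states", data=np.column_stack(
                        [rec.states.theta, rec.states.theta_dot]))
                    if rec.torques is not None:
                        b.create_dataset("torques", data=rec.torques)


def load_cohort(path) -> CohortDataset:
    """Read a cohort dataset written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        metrics = _read_table(f["metrics"])
        questionnaires = _read_table(f["questionnaires"])
        config = json.loads(f.attrs["config"])
        seed = int(f.attrs["seed"])
        profiles = []
        recordings = {}
        for pid in sorted(f["participants"]):
            g = f["participants"][pid]
            attrs = {k: g.attrs[k] for k in g.attrs}
            profiles.append(ParticipantProfile(
                participant_id=str(attrs["participant_id"]),
                group=str(attrs["group"]),
                skill0=float(attrs["skill0"]),
                learning_rate=float(attrs["learning_rate"]),
                phase_lead=float(attrs["phase_lead"]),
                motor_noise_sd=float(attrs["motor_noise_sd"]),
                feedback_delay=float(attrs["feedback_delay"]),
                rng_seed=int(attrs["rng_seed"])))
            if "blocks" in g:
                recs = {}
                for key in g["blocks"]:
                    b = g["blocks"][key]
                    pivot_arr = b["pivot"][()]
                    pivot = PivotTrajectory(*[pivot_arr[:, i]
                                              for i in range(7)])
                    state_arr = b["states"][()]
                    trace = PendulumTrace(pivot_arr[:, 0], state_arr[:, 0],
                                          state_arr[:, 1])
                    torques = b["torques"][()] if "torques" in b else None
                    recs[int(key)] = BlockRecording(
                        modality=Modality(hr=bool(b.attrs["hr"]),
                                          ws=bool(b.attrs["ws"])),
                        phase_label=str(b.attrs["phase_label"]),
                        rod_length=float(b.attrs["rod_length"]),
                        pivot=pivot, states=trace, torques=torques,
                        score=float(b.attrs["score"]) if "score" in b.attrs else None,
                        block_index=int(key),
                        training_position=int(b.attrs["training_position"])
                        if "training_position" in b.attrs else None)
                recordings[pid] = recs
    return CohortDataset(profiles=profiles, metrics=metrics,
                         questionnaires=questionnaires, seed=seed,
                         config=config,
                         recordings=recordings or None)
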