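"""Data model and CSV/JSON readers and writers for gaze sessions.

CSV is the interchange format: one row per sample (gaze stream) or per
event (event log).  Timestamps are seconds from recording start.  Invalid
samples carry the placeholder direction (0, 0, 1) with ``valid = 0``; the
flag, not the value, is authoritative, because the eye tracker interpolates
positions for dropped samples while validity derives from pupil samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .classify import ThresholdSet

__all__ = [
    "GazeRecording",
    "EventLog",
    "PipelineConfig",
    "FormatError",
    "DataError",
    "PLACEHOLDER_DIR",
    "EVENT_KINDS",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_config",
    "write_config",
    "write_speeds",
]

PLACEHOLDER_DIR = np.array([0.0, 0.0, 1.0])

EVENT_KINDS = ("trial_start", "cue_onset", "target_onset", "response")

RECORDING_COLUMNS = [
    "t", "eye_x", "eye_y", "eye_z",
    "head_qw", "head_qx", "head_qy", "head_qz",
    "pos_x", "pos_y", "pos_z", "valid",
]

EVENT_COLUMNS = [
    "t", "kind", "trial_id", "condition_motion", "condition_eccentricity",
    "cue_distance_m", "target_dir", "response_side",
    "cued_disk_index", "distractor_disk_index",
]


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class DataError(ValueError):
    """A file is schema-conformant but its contents violate an invariant."""


@dataclass
class GazeRecording:
    """Per-sample eye-in-head direction, head pose, and validity.

    t : seconds, strictly increasing, nominally 1/120 s apart.
    eye_dir : (n, 3) unit vectors, head frame.
    head_quat : (n, 4) unit quaternions (w, x, y, z), head-to-world.
    head_pos : (n, 3) meters, world frame.
    valid : (n,) bool; invalid samples hold the placeholder direction.
    pupil_mm : optional (n,) pupil diameter, millimeters.
    """

    t: np.ndarray
    eye_dir: np.ndarray
    head_quat: np.ndarray
    head_pos: np.ndarray
    valid: np.ndarray
    pupil_mm: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.t)

    def validate(self) -> "GazeRecording":
        if self.n and np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        v = self.valid.astype(bool)
        if v.any():
            norms = np.linalg.norm(self.eye_dir[v], axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise DataError("valid eye directions must be unit vectors")
        if self.n:
            qn = np.linalg.norm(self.head_quat, axis=1)
            if np.any(np.abs(qn - 1.0) > 1e-6):
                raise DataError("head quaternions must be unit quaternions")
        return self


@dataclass
class EventLog:
    """Session events as a DataFrame with the event-CSV schema."""

    events: pd.DataFrame

    def validate(self) -> "EventLog":
        df = self.events
        unknown = set(df["kind"]) - set(EVENT_KINDS)
        if unknown:
            raise DataError(f"unknown event kinds: {sorted(unknown)}")
        if np.any(np.diff(df["t"].to_numpy(dtype=float)) < 0):
            raise DataError("event times must be non-decreasing")
        for trial_id, g in df.groupby("trial_id"):
            times = {k: g.loc[g["kind"] == k, "t"].min() for k in
                     ("cue_onset", "target_onset", "response")}
            order = [times[k] for k in ("cue_onset", "target_onset", "response")
                     if pd.notna(times[k])]
            if any(a >= b for a, b in zip(order, order[1:])):
                raise DataError(
                    f"trial {trial_id}: cue/target/response out of order")
        return self

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)


@dataclass
class PipelineConfig:
    """Tunable parameters of the classification pipeline.

    Durations are seconds, speeds deg/s.  Defaults follow the published
    pipeline: 5-sample median filter, 40 ms noise padding, 100 ms epochs,
    20 ms minimum saccade duration, 3 deg minimum amplitude, 1,000 deg/s
    peak-velocity ceiling, and a 20 deg/s eye-speed exclusion for on-target
    gaze-speed averages.
    """

    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    median_window: int = 5
    noise_pad: float = 0.040
    epoch_length: float = 0.100
    min_saccade_duration: float = 0.020
    min_amplitude: float = 3.0
    max_peak_velocity: float = 1000.0
    pursuit_eye_speed_exclusion: float = 20.0

    def __post_init__(self) -> None:
        for name in ("noise_pad", "epoch_length", "min_saccade_duration",
                     "min_amplitude", "max_peak_velocity",
                     "pursuit_eye_speed_exclusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.median_window < 1:
            raise ValueError("median_window must be positive")


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_recording(path: Union[str, Path]) -> GazeRecording:
    """Read a gaze-stream CSV.

    Rows with missing eye fields become ``valid = False`` with the
    placeholder direction.  Non-monotone timestamps raise :class:`DataError`
    (files are never silently reordered); a missing column raises
    :class:`FormatError` naming the column.
    """
    df = pd.read_csv(path)
    _require_columns(df, RECORDING_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    eye = df[["eye_x", "eye_y", "eye_z"]].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=float).astype(bool)
    missing = np.isnan(eye).any(axis=1)
    valid = valid & ~missing
    eye[~valid] = PLACEHOLDER_DIR
    quat = df[["head_qw", "head_qx", "head_qy", "head_qz"]].to_numpy(dtype=float)
    pos = df[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float)
    pupil = (df["pupil_mm"].to_numpy(dtype=float)
             if "pupil_mm" in df.columns else None)
    return GazeRecording(t=t, eye_dir=eye, head_quat=quat, head_pos=pos,
                         valid=valid, pupil_mm=pupil).validate()


def write_recording(rec: GazeRecording, path: Union[str, Path]) -> None:
    """Write a gaze-stream CSV; invalid samples get the placeholder direction."""
    eye = rec.eye_dir.copy()
    eye[~rec.valid.astype(bool)] = PLACEHOLDER_DIR
    data = {
        "t": rec.t,
        "eye_x": eye[:, 0], "eye_y": eye[:, 1], "eye_z": eye[:, 2],
        "head_qw": rec.head_quat[:, 0], "head_qx": rec.head_quat[:, 1],
        "head_qy": rec.head_quat[:, 2], "head_qz": rec.head_quat[:, 3],
        "pos_x": rec.head_pos[:, 0], "pos_y": rec.head_pos[:, 1],
        "pos_z": rec.head_pos[:, 2],
        "valid": rec.valid.astype(int),
    }
    if rec.pupil_mm is not None:
        data["pupil_mm"] = rec.pupil_mm
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_events(path: Union[str, Path]) -> EventLog:
    """Read an event-log CSV; out-of-order event times raise DataError."""
    df = pd.read_csv(path)
    _require_columns(df, ["t", "kind", "trial_id"], path)
    for c in EVENT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return EventLog(events=df[EVENT_COLUMNS].copy()).validate()


def write_events(log: EventLog, path: Union[str, Path]) -> None:
    df = log.events.copy()
    for c in EVENT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df[EVENT_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a pipeline config from a JSON key-value file."""
    with open(path) as fh:
        raw = json.load(fh)
    thr = ThresholdSet(**raw.pop("thresholds", {}))
    return PipelineConfig(thresholds=thr, **raw)


def write_config(cfg: PipelineConfig, path: Union[str, Path]) -> None:
    raw = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


def write_speeds(speeds, path: Union[str, Path]) -> None:
    """Write a SpeedSeries as CSV (t, eye_speed, head_speed, gaze_speed, usable)."""
    speeds.to_frame().to_csv(path, index=False, float_format="%.12g")
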