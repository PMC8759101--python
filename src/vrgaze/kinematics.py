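"""Angular speed series from raw gaze and head-pose samples.

Conventions
-----------
* Eye speed: angular velocity of the eye relative to the head (deg/s).
* Head speed: angular velocity of the head relative to the world (deg/s).
* Gaze speed: angular velocity of the world-frame line of sight, i.e. the
  head rotation applied to the eye-in-head direction (deg/s).
* Speeds are backward differences assigned to the later sample; the first
  sample copies the second.
* Coordinates are left-handed, y-up, z-forward (game-engine convention);
  quaternions are (w, x, y, z), head-to-world.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.spatial.transform import Rotation

if TYPE_CHECKING:  # pragma: no cover
    from .io import GazeRecording, PipelineConfig

__all__ = [
    "SpeedSeries",
    "gaze_direction",
    "angular_speed",
    "head_angular_speed",
    "median_filter",
    "mask_invalid",
    "compute_speeds",
    "resample_pose",
]


@dataclass
class SpeedSeries:
    """Per-sample eye, head, and gaze angular speeds with a usability mask."""

    t: np.ndarray           # seconds
    eye_speed: np.ndarray   # deg/s, eye relative to head
    head_speed: np.ndarray  # deg/s, head relative to world
    gaze_speed: np.ndarray  # deg/s, line of sight relative to world
    usable: np.ndarray      # bool, after noise padding

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt_nominal(self) -> float:
        return float(np.median(np.diff(self.t))) if self.n > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "eye_speed": self.eye_speed,
            "head_speed": self.head_speed, "gaze_speed": self.gaze_speed,
            "usable": self.usable.astype(int),
        })


def gaze_direction(eye_dir: np.ndarray, head_quat: np.ndarray) -> np.ndarray:
    """Rotate eye-in-head direction(s) into the world frame.

    Accepts a single (3,) vector with a (4,) quaternion or stacked (n, 3)
    and (n, 4) arrays.  Quaternions are (w, x, y, z).
    """
    eye_dir = np.asarray(eye_dir, dtype=float)
    head_quat = np.asarray(head_quat, dtype=float)
    norms = np.linalg.norm(eye_dir, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("eye direction must have non-zero norm")
    q_xyzw = np.concatenate(
        [head_quat[..., 1:], head_quat[..., :1]], axis=-1)
    out = Rotation.from_quat(q_xyzw).apply(eye_dir)
    out /= np.linalg.norm(out, axis=-1, keepdims=True)
    return out


def angular_speed(dirs: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Angular speed (deg/s) of a direction time series.

    ``speed[i]`` is the angle between ``dirs[i-1]`` and ``dirs[i]`` divided
    by ``t[i] - t[i-1]``; the first sample copies the second.
    """
    dirs = np.asarray(dirs, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    a, b = dirs[:-1], dirs[1:]
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.sum(a * b, axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    speed = np.empty(len(t))
    speed[1:] = ang / dt
    speed[0] = speed[1]
    return speed


def head_angular_speed(quats: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Angular speed (deg/s) of an orientation time series.

    Geodesic rotation angle between successive quaternions divided by dt;
    insensitive to the quaternion double cover (q and -q are the same
    orientation).  Same backward-difference convention as
    :func:`angular_speed`.
    """
    quats = np.asarray(quats, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    # relative rotation q_rel = conj(q1) * q2; angle = 2*atan2(|vec|, |w|)
    w1, v1 = quats[:-1, 0], quats[:-1, 1:]
    w2, v2 = quats[1:, 0], quats[1:, 1:]
    w = w1 * w2 + np.sum(v1 * v2, axis=-1)
    vec = (w1[:, None] * v2 - w2[:, None] * v1 - np.cross(v1, v2))
    ang = 2.0 * np.degrees(np.arctan2(np.linalg.norm(vec, axis=-1), np.abs(w)))
    speed = np.empty(len(t))
    speed[1:] = ang / dt
    speed[0] = speed[1]
    return speed


def median_filter(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered running median; edges use shrunken windows.

    The five-sample (40 ms at 120 Hz) median smooths speed traces before
    thresholding.  No padding values are invented at the edges.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def mask_invalid(valid: np.ndarray, t: np.ndarray, pad: float = 0.040) -> np.ndarray:
    """Usability mask: invalid samples plus a padding margin are unusable.

    Every sample within ``pad`` seconds of an invalid sample is marked
    unusable.  The pad is rounded up to whole samples (5 samples each side
    at 120 Hz for the default 40 ms) so the full margin is always covered.
    """
    valid = np.asarray(valid, dtype=bool)
    t = np.asarray(t, dtype=float)
    if len(valid) != len(t):
        raise ValueError("valid and t must have the same length")
    if valid.all():
        return valid.copy()
    if len(t) > 1:
        dt = float(np.median(np.diff(t)))
        n_pad = int(np.ceil(pad / dt - 1e-9))
    else:
        n_pad = 0
    bad = ~valid
    if n_pad > 0:
        bad = binary_dilation(bad, structure=np.ones(2 * n_pad + 1, dtype=bool))
    return ~bad


def compute_speeds(rec: "GazeRecording", cfg: "PipelineConfig") -> SpeedSeries:
    """Masked, median-filtered eye/head/gaze speed series for a recording."""
    gaze_dirs = gaze_direction(rec.eye_dir, rec.head_quat)
    eye = median_filter(angular_speed(rec.eye_dir, rec.t), cfg.median_window)
    head = median_filter(head_angular_speed(rec.head_quat, rec.t), cfg.median_window)
    gaze = median_filter(angular_speed(gaze_dirs, rec.t), cfg.median_window)
    usable = mask_invalid(rec.valid, rec.t, cfg.noise_pad)
    return SpeedSeries(t=rec.t.copy(), eye_speed=eye, head_speed=head,
                       gaze_speed=gaze, usable=usable)


def resample_pose(
    t_src: np.ndarray,
    quats: np.ndarray,
    pos: np.ndarray,
    t_dst: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour resampling of a head-pose stream onto eye timestamps.

    The headset renders at 90 Hz while the eye tracker samples at 120 Hz;
    nearest-neighbour alignment introduces at most half a source sample
    period (~5.6 ms) of skew.
    """
    t_src = np.asarray(t_src, dtype=float)
    t_dst = np.asarray(t_dst, dtype=float)
    idx = np.searchsorted(t_src, t_dst)
    idx = np.clip(idx, 1, len(t_src) - 1)
    left = t_dst - t_src[idx - 1]
    right = t_src[idx] - t_dst
    nearest = np.where(left <= right, idx - 1, idx)
    return np.asarray(quats)[nearest], np.asarray(pos)[nearest]
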