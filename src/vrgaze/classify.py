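"""Head-speed-scaled saccade detection and intersaccadic epoch classification.

The classifier applies a dynamic velocity threshold to eye and gaze speed,

    threshold_scaled = (1 + v_head / 60) * threshold,

where ``v_head`` is the head's angular speed (deg/s) at the moment of the
comparison.  Saccades are detected first: maximal runs of samples whose
eye-in-head speed exceeds the scaled saccade threshold, kept when the run
lasts at least 20 ms.  Saccades under 3 deg of gaze amplitude or with a peak
velocity of 1,000 deg/s or more are retained but relabeled
``excluded_saccade``.  The intervals between saccades are tiled with 100 ms
epochs and each epoch is labeled by a decision tree over its mean gaze, eye,
and head speeds: quiet gaze splits into fixation vs. VOR on head speed;
moving gaze splits into head pursuit (quiet eye), smooth pursuit (quiet
head), or smooth pursuit with compensatory VOR (both moving).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from . import kinematics

if TYPE_CHECKING:  # pragma: no cover
    from .io import GazeRecording, PipelineConfig
    from .kinematics import SpeedSeries

__all__ = [
    "ThresholdSet",
    "Segment",
    "EPOCH_LABELS",
    "scale_threshold",
    "detect_saccades",
    "saccade_metrics",
    "filter_saccades",
    "partition_intersaccadic",
    "classify_epoch",
    "classify_recording",
    "segments_to_frame",
    "segment_labels_per_sample",
]

#: Labels an intersaccadic epoch can receive.
EPOCH_LABELS = ("fixation", "vor", "smooth_pursuit", "head_pursuit", "sp_vor")

ALL_LABELS = ("saccade", "excluded_saccade", "noise", "unclassified") + EPOCH_LABELS


@dataclass
class ThresholdSet:
    """Velocity thresholds (deg/s) of the classification flow chart.

    ``theta_saccade``, ``theta_lowgaze`` and ``theta_loweye`` are the
    stationary-head values and are scaled by head speed before use;
    ``theta_head`` is a fixed head-speed criterion and is never scaled
    (scaling a head threshold by head speed would be self-referential).
    ``theta_highgaze`` is carried for completeness but unused by the
    default decision tree.
    """

    theta_saccade: float = 35.0
    theta_lowgaze: float = 10.0
    theta_head: float = 7.0
    theta_loweye: float = 10.0
    theta_highgaze: Optional[float] = None
    scaling_denominator: float = 60.0

    def __post_init__(self) -> None:
        for name in ("theta_saccade", "theta_lowgaze", "theta_head",
                     "theta_loweye", "scaling_denominator"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.theta_lowgaze >= self.theta_saccade:
            raise ValueError("theta_lowgaze must be below theta_saccade")


@dataclass
class Segment:
    """A labeled, contiguous span of samples.

    ``i_start``/``i_end`` are inclusive sample indices into the source
    recording.  ``t_start``/``t_end`` follow the sample-ownership
    convention: sample ``i`` owns the interval ``(t[i-1], t[i]]``, so a
    segment's span is ``(t[i_start-1], t[i_end]]``.
    """

    i_start: int
    i_end: int
    t_start: float
    t_end: float
    label: str
    amplitude: Optional[float] = None      # deg, saccades only
    peak_velocity: Optional[float] = None  # deg/s, saccades only
    mean_eye_speed: Optional[float] = None   # deg/s, epochs only
    mean_head_speed: Optional[float] = None  # deg/s, epochs only
    mean_gaze_speed: Optional[float] = None  # deg/s, epochs only
    interval_id: Optional[int] = None        # intersaccadic interval, epochs only

    @property
    def n_samples(self) -> int:
        return self.i_end - self.i_start + 1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def scale_threshold(v_head: float, base: float, denominator: float = 60.0) -> float:
    """Scale a stationary-head threshold by the current head speed.

    Returns ``(1 + v_head / denominator) * base``; equals ``base`` for a
    stationary head and increases linearly with head speed.
    """
    v_head = np.asarray(v_head, dtype=float)
    if np.any(v_head < 0):
        raise ValueError("head speed must be non-negative")
    out = (1.0 + v_head / denominator) * base
    return float(out) if out.ndim == 0 else out


def _own_start(t: np.ndarray, i: int, dt_nominal: float) -> float:
    """Start time of the interval owned by sample ``i``."""
    return float(t[i - 1]) if i > 0 else float(t[i] - dt_nominal)


def detect_saccades(
    speeds: "SpeedSeries",
    thr: ThresholdSet,
    min_duration: float = 0.020,
) -> list[Segment]:
    """Find saccades as supra-threshold runs of eye speed.

    A sample is saccadic when it is usable and its (filtered) eye speed
    strictly exceeds ``(1 + head_speed/60) * theta_saccade`` evaluated with
    the per-sample head speed.  Maximal contiguous saccadic runs are kept
    when their duration is at least ``min_duration``; runs are never bridged
    across unusable samples.
    """
    t = speeds.t
    if len(t) == 0:
        return []
    scaled = scale_threshold(speeds.head_speed, thr.theta_saccade,
                             thr.scaling_denominator)
    hot = speeds.usable & (speeds.eye_speed > scaled)
    dt_nom = speeds.dt_nominal
    segs: list[Segment] = []
    for i0, i1 in _runs(hot):
        t_start = _own_start(t, i0, dt_nom)
        t_end = float(t[i1])
        if t_end - t_start >= min_duration - 1e-12:
            segs.append(Segment(i0, i1, t_start, t_end, "saccade"))
    return segs


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of maximal True runs."""
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def saccade_metrics(
    seg: Segment,
    rec: "GazeRecording",
    speeds: "SpeedSeries",
) -> Segment:
    """Attach amplitude and peak velocity to a detected saccade.

    Amplitude is the angle between the world-frame gaze directions at the
    segment's first and last usable samples (the size of the gaze shift,
    which is what the 3 deg inclusion rule targets); peak velocity is the
    maximum eye speed within the segment.
    """
    idx = np.arange(seg.i_start, seg.i_end + 1)
    usable_idx = idx[speeds.usable[idx]]
    if usable_idx.size == 0:
        usable_idx = idx
    first, last = int(usable_idx[0]), int(usable_idx[-1])
    g0 = kinematics.gaze_direction(rec.eye_dir[first], rec.head_quat[first])
    g1 = kinematics.gaze_direction(rec.eye_dir[last], rec.head_quat[last])
    amplitude = float(np.degrees(
        np.arctan2(np.linalg.norm(np.cross(g0, g1)), np.dot(g0, g1))))
    peak = float(np.max(speeds.eye_speed[seg.i_start:seg.i_end + 1]))
    return replace(seg, amplitude=amplitude, peak_velocity=peak)


def filter_saccades(
    segs: Sequence[Segment],
    min_amplitude: float = 3.0,
    max_peak_velocity: float = 1000.0,
) -> list[Segment]:
    """Relabel implausible saccades as ``excluded_saccade``.

    A saccade is excluded when its amplitude is below ``min_amplitude`` or
    its peak velocity reaches ``max_peak_velocity``; nothing is deleted.
    """
    out = []
    for s in segs:
        if s.label not in ("saccade", "excluded_saccade"):
            out.append(s)
            continue
        if s.amplitude is None or s.peak_velocity is None:
            raise ValueError("saccade metrics must be computed before filtering")
        bad = s.amplitude < min_amplitude or s.peak_velocity >= max_peak_velocity
        out.append(replace(s, label="excluded_saccade" if bad else "saccade"))
    return out


def partition_intersaccadic(
    segs: Sequence[Segment],
    speeds: "SpeedSeries",
    epoch_length: float = 0.100,
) -> list[Segment]:
    """Tile the intersaccadic intervals with fixed-length epochs.

    Each maximal run of usable samples not claimed by a (kept or excluded)
    saccade is tiled left-to-right with ``epoch_length`` windows.  A
    trailing remainder of at least half an epoch becomes its own short
    epoch; a smaller remainder is merged into the preceding epoch; an
    interval shorter than half an epoch with no preceding epoch is labeled
    ``unclassified``.  Returned segments carry ``interval_id`` and a
    placeholder label (``"epoch"`` / ``"unclassified"``).
    """
    t = speeds.t
    n = len(t)
    dt_nom = speeds.dt_nominal
    taken = np.zeros(n, dtype=bool)
    for s in segs:
        taken[s.i_start:s.i_end + 1] = True
    free = speeds.usable & ~taken
    half = epoch_length / 2.0
    out: list[Segment] = []
    for interval_id, (i0, i1) in enumerate(_runs(free)):
        start = _own_start(t, i0, dt_nom)
        end = float(t[i1])
        duration = end - start
        n_full = int(np.floor(duration / epoch_length + 1e-9))
        rem = duration - n_full * epoch_length
        if n_full == 0 and rem < half - 1e-9:
            out.append(Segment(i0, i1, start, end, "unclassified",
                               interval_id=interval_id))
            continue
        widths = [epoch_length] * n_full
        if rem > 1e-9:
            if rem >= half - 1e-9 or n_full == 0:
                widths.append(rem)
            else:
                widths[-1] += rem
        edges = start + np.cumsum(widths)
        edges[-1] = end  # guard float drift at the interval end
        rel = t[i0:i1 + 1]
        # sample owns (t[i-1], t[i]]: epoch k holds samples with t <= edges[k]
        k = np.searchsorted(edges, rel - 1e-9, side="left")
        for e in range(len(widths)):
            sel = np.flatnonzero(k == e)
            if sel.size == 0:
                continue
            j0, j1 = i0 + int(sel[0]), i0 + int(sel[-1])
            out.append(Segment(j0, j1, _own_start(t, j0, dt_nom), float(t[j1]),
                               "epoch", interval_id=interval_id))
    return out


def classify_epoch(
    mean_gaze: float,
    mean_eye: float,
    mean_head: float,
    thr: ThresholdSet,
) -> str:
    """Label one intersaccadic epoch from its mean speeds.

    Ties at exact threshold equality resolve to the slower branch
    (fixation / VOR / head pursuit / smooth pursuit).
    """
    low_gaze = scale_threshold(mean_head, thr.theta_lowgaze, thr.scaling_denominator)
    if mean_gaze <= low_gaze:
        return "fixation" if mean_head <= thr.theta_head else "vor"
    low_eye = scale_threshold(mean_head, thr.theta_loweye, thr.scaling_denominator)
    if mean_eye <= low_eye:
        return "head_pursuit"
    return "smooth_pursuit" if mean_head <= thr.theta_head else "sp_vor"


def classify_recording(
    rec: "GazeRecording",
    cfg: "PipelineConfig",
) -> list[Segment]:
    """Run the full pipeline on a recording.

    Masking, speed computation and median filtering, saccade detection and
    exclusion, epoch tiling and epoch labeling; unusable stretches become
    ``noise`` segments.  The returned segments are ordered and tile every
    sample of the recording exactly once.
    """
    if rec.n < 2:
        raise ValueError("recording must contain at least 2 samples")
    speeds = kinematics.compute_speeds(rec, cfg)
    thr = cfg.thresholds
    saccades = detect_saccades(speeds, thr, cfg.min_saccade_duration)
    saccades = [saccade_metrics(s, rec, speeds) for s in saccades]
    saccades = filter_saccades(saccades, cfg.min_amplitude, cfg.max_peak_velocity)
    epochs = partition_intersaccadic(saccades, speeds, cfg.epoch_length)

    labeled_epochs: list[Segment] = []
    for e in epochs:
        if e.label == "unclassified":
            labeled_epochs.append(e)
            continue
        sl = slice(e.i_start, e.i_end + 1)
        use = speeds.usable[sl]
        mg = float(np.mean(speeds.gaze_speed[sl][use]))
        me = float(np.mean(speeds.eye_speed[sl][use]))
        mh = float(np.mean(speeds.head_speed[sl][use]))
        label = classify_epoch(mg, me, mh, thr)
        labeled_epochs.append(replace(
            e, label=label, mean_gaze_speed=mg, mean_eye_speed=me,
            mean_head_speed=mh))

    # unusable samples -> noise segments
    segs = saccades + labeled_epochs
    taken = np.zeros(rec.n, dtype=bool)
    for s in segs:
        taken[s.i_start:s.i_end + 1] = True
    dt_nom = speeds.dt_nominal
    for i0, i1 in _runs(~taken):
        segs.append(Segment(i0, i1, _own_start(rec.t, i0, dt_nom),
                            float(rec.t[i1]), "noise"))
    segs.sort(key=lambda s: s.i_start)
    return segs


def segments_to_frame(segs: Sequence[Segment]) -> pd.DataFrame:
    """Segments as a DataFrame matching the segment CSV interface."""
    return pd.DataFrame([{
        "t_start": s.t_start, "t_end": s.t_end, "label": s.label,
        "amplitude": s.amplitude, "peak_velocity": s.peak_velocity,
        "mean_eye_speed": s.mean_eye_speed,
        "mean_head_speed": s.mean_head_speed,
        "mean_gaze_speed": s.mean_gaze_speed,
        "i_start": s.i_start, "i_end": s.i_end,
        "interval_id": s.interval_id,
    } for s in segs])


def segment_labels_per_sample(segs: Sequence[Segment], n: int) -> np.ndarray:
    """Expand a segment tiling to one label per sample."""
    labels = np.full(n, "unclassified", dtype=object)
    for s in segs:
        labels[s.i_start:s.i_end + 1] = s.label
    return labels
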