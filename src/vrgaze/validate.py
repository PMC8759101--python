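"""Ray-cast foveation labels and classification validation statistics.

An imaginary ray from the eye along the instantaneous world-frame gaze
direction is intersected with the scene (cross and disks, modeled as
spheres); the nearest hit names the foveated object.  Because object
positions and speeds are known exactly, samples foveating a stationary
object (the recentering cross, static-trial disks) *should* never be
labeled pursuit, while samples foveating dynamic-trial disks should be —
comparing the two pursuit-label rates quantifies the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import kinematics
from .classify import Segment, segment_labels_per_sample
from .io import EventLog, GazeRecording
from .kinematics import SpeedSeries
from .paradigm import WorldLayout, disk_label, disk_position

__all__ = [
    "RayCastSeries",
    "ValidationReport",
    "PURSUIT_LABELS",
    "SP_LABELS",
    "raycast",
    "raycast_series",
    "pursuit_validation",
    "target_interval_gaze_speed",
    "main_sequence_stats",
    "reaction_times",
    "valid_sample_fraction",
    "classification_agreement",
    "saccade_recovery",
]

#: Labels counted as "pursuit" in the combined misclassification figure
#: (smooth pursuit, smooth pursuit with compensatory VOR, head pursuit).
PURSUIT_LABELS = ("smooth_pursuit", "sp_vor", "head_pursuit")
#: Labels counted as smooth pursuit proper (including compensatory VOR).
SP_LABELS = ("smooth_pursuit", "sp_vor")


@dataclass
class RayCastSeries:
    """Per-sample foveated-object label and hit distance (m; NaN = background)."""

    t: np.ndarray
    label: np.ndarray
    hit_distance: np.ndarray

    @property
    def n(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "label": self.label,
                             "hit_distance": self.hit_distance})


@dataclass
class ValidationReport:
    """Pursuit-label rates on static vs. moving foveated objects.

    Percentages are over usable (non-noise) samples; a category with no
    samples reports ``None`` rather than zero.
    """

    pct_pursuit_on_static: Optional[float]
    pct_pursuit_on_moving: Optional[float]
    pct_sp_on_static: Optional[float]
    pct_sp_on_moving: Optional[float]
    by_condition: dict = field(default_factory=dict)
    label_breakdown: dict = field(default_factory=dict)
    confusion: Optional[dict] = None
    n_static_samples: int = 0
    n_moving_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "pct_pursuit_on_static": self.pct_pursuit_on_static,
            "pct_pursuit_on_moving": self.pct_pursuit_on_moving,
            "pct_sp_on_static": self.pct_sp_on_static,
            "pct_sp_on_moving": self.pct_sp_on_moving,
            "by_condition": self.by_condition,
            "label_breakdown": self.label_breakdown,
            "confusion": self.confusion,
            "n_static_samples": self.n_static_samples,
            "n_moving_samples": self.n_moving_samples,
        }


def raycast(
    gaze_origin: np.ndarray,
    gaze_dir_world: np.ndarray,
    objects: Sequence[tuple],
    layout: Optional[WorldLayout] = None,
) -> tuple[str, float]:
    """Nearest object hit by the gaze ray, or ``("background", nan)``.

    ``objects`` is a sequence of ``(label, center, radius)`` with centers in
    the same frame as ``gaze_origin``.  Objects are spheres; the nearest
    intersection along the ray wins.  Only the ray's direction matters.
    """
    o = np.asarray(gaze_origin, dtype=float)
    d = np.asarray(gaze_dir_world, dtype=float)
    d = d / np.linalg.norm(d)
    best = ("background", np.nan)
    best_t = np.inf
    for label, center, radius in objects:
        oc = np.asarray(center, dtype=float) - o
        tca = float(np.dot(oc, d))
        if tca <= 0:
            continue
        d2 = float(np.dot(oc, oc)) - tca * tca
        if d2 > radius * radius:
            continue
        thc = np.sqrt(radius * radius - d2)
        t_hit = tca - thc
        if t_hit < best_t:
            best_t = t_hit
            best = (label, t_hit)
    return best


def raycast_series(
    rec: GazeRecording,
    events: EventLog,
    layout: WorldLayout,
) -> RayCastSeries:
    """Ray-cast every sample of a session against its trial's scene.

    The scene per trial holds the observer-locked recentering cross and
    both disk rings at the trial's cue distance; dynamic-trial disks are
    world-fixed while the observer closes at 5 m/s, so their
    observer-relative position follows :func:`~vrgaze.paradigm.disk_position`.
    """
    gaze = kinematics.gaze_direction(rec.eye_dir, rec.head_quat)
    n = rec.n
    labels = np.full(n, "background", dtype=object)
    hit = np.full(n, np.nan)

    starts = events.of_kind("trial_start")
    cues = events.of_kind("cue_onset").set_index("trial_id")["t"]
    t_starts = starts["t"].to_numpy(dtype=float)
    bounds = np.searchsorted(rec.t, t_starts)
    bounds = np.append(bounds, n)

    for k, row in starts.iterrows():
        i0, i1 = int(bounds[k]), int(bounds[k + 1])
        if i1 <= i0:
            continue
        sl = slice(i0, i1)
        tc = rec.t[sl] - float(cues.loc[row["trial_id"]])
        motion = row["condition_motion"]
        cue_dist = float(row["cue_distance_m"])
        objs = []  # (label, rel_centers (m,3), radius)
        cross_rel = np.tile([0.0, 0.0, layout.cross_distance], (i1 - i0, 1))
        objs.append(("cross", cross_rel, layout.cross_size / 2.0))
        for ecc in layout.ring_eccentricities:
            for idx in range(layout.disks_per_ring):
                rel = _disk_relative(layout, ecc, idx, cue_dist, tc, motion)
                objs.append((disk_label(ecc, idx), rel,
                             layout.disk_diameter / 2.0))
        g = gaze[sl]
        best_t = np.full(i1 - i0, np.inf)
        for label, rel, radius in objs:
            tca = np.einsum("ij,ij->i", rel, g)
            d2 = np.einsum("ij,ij->i", rel, rel) - tca * tca
            ok = (tca > 0) & (d2 <= radius * radius)
            t_hit = np.where(ok, tca - np.sqrt(np.maximum(
                radius * radius - d2, 0.0)), np.inf)
            closer = t_hit < best_t
            best_t = np.where(closer, t_hit, best_t)
            sel = np.flatnonzero(closer) + i0
            labels[sel] = label
            hit[sel] = t_hit[closer]
    return RayCastSeries(t=rec.t.copy(), label=labels, hit_distance=hit)


def _disk_relative(layout, ecc, idx, cue_dist, tc, motion) -> np.ndarray:
    """Observer-relative disk centers over a trial's samples."""
    if motion == "dynamic":
        p0 = disk_position(layout, ecc, idx, cue_dist, 0.0, "dynamic")
        rel = np.tile(p0, (len(tc), 1))
        rel[:, 2] = cue_dist - layout.observer_speed * tc
        return rel
    p0 = disk_position(layout, ecc, idx, cue_dist, 0.0, "static")
    return np.tile(p0, (len(tc), 1))


def _per_sample_trial(t: np.ndarray, events: EventLog) -> pd.DataFrame:
    """Trial attributes per sample (motion, eccentricity, cued disk label)."""
    starts = events.of_kind("trial_start")
    t_starts = starts["t"].to_numpy(dtype=float)
    idx = np.searchsorted(t_starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    cued = np.array([
        disk_label(20.0 if e == "peripheral" else 6.0, int(d))
        for e, d in zip(starts["condition_eccentricity"],
                        starts["cued_disk_index"])], dtype=object)
    return pd.DataFrame({
        "trial_id": starts["trial_id"].to_numpy()[idx],
        "motion": starts["condition_motion"].to_numpy()[idx],
        "eccentricity": starts["condition_eccentricity"].to_numpy()[idx],
        "cued_label": cued[idx],
    })


def _pct(mask_num: np.ndarray, mask_den: np.ndarray) -> Optional[float]:
    den = int(mask_den.sum())
    if den == 0:
        return None
    return 100.0 * float((mask_num & mask_den).sum()) / den


def pursuit_validation(
    segments: Sequence[Segment],
    ray: RayCastSeries,
    events: EventLog,
    truth=None,
) -> ValidationReport:
    """Pursuit-label rates on static vs. moving foveated objects.

    Static objects are the cross and static-trial disks; moving objects are
    dynamic-trial disks.  The combined pursuit figure counts smooth
    pursuit, smooth pursuit with compensatory VOR, and head pursuit; the
    smooth-pursuit figure counts the first two.  ``by_condition`` holds the
    smooth-pursuit rate on the *cued* disk split by motion and
    eccentricity.  With ground truth supplied, a predicted-vs-truth
    confusion table over usable samples is attached.
    """
    n = ray.n
    pred = segment_labels_per_sample(segments, n)
    usable = pred != "noise"
    info = _per_sample_trial(ray.t, events)

    is_disk = np.array([str(l).startswith("disk:") for l in ray.label])
    motion = info["motion"].to_numpy()
    on_static = usable & ((ray.label == "cross") | (is_disk & (motion == "static")))
    on_moving = usable & is_disk & (motion == "dynamic")
    is_pursuit = np.isin(pred, PURSUIT_LABELS)
    is_sp = np.isin(pred, SP_LABELS)

    by_condition = {}
    on_cued = usable & (ray.label == info["cued_label"].to_numpy())
    for mo in ("static", "dynamic"):
        for ecc in ("parafoveal", "peripheral", "all"):
            sel = on_cued & (motion == mo)
            if ecc != "all":
                sel = sel & (info["eccentricity"].to_numpy() == ecc)
            by_condition[f"{mo}_{ecc}"] = {
                "pct_smooth_pursuit": _pct(is_sp, sel),
                "pct_pursuit": _pct(is_pursuit, sel),
                "n_samples": int(sel.sum()),
            }

    breakdown = {}
    for name, sel in (("on_static", on_static), ("on_moving", on_moving)):
        counts = pd.Series(pred[sel]).value_counts().to_dict()
        breakdown[name] = {str(k): int(v) for k, v in counts.items()}

    confusion = None
    if truth is not None:
        tl = truth.label if hasattr(truth, "label") else np.asarray(truth)
        confusion = {}
        for p, tr in zip(pred[usable], tl[usable]):
            confusion.setdefault(str(tr), {})
            confusion[str(tr)][str(p)] = confusion[str(tr)].get(str(p), 0) + 1

    return ValidationReport(
        pct_pursuit_on_static=_pct(is_pursuit, on_static),
        pct_pursuit_on_moving=_pct(is_pursuit, on_moving),
        pct_sp_on_static=_pct(is_sp, on_static),
        pct_sp_on_moving=_pct(is_sp, on_moving),
        by_condition=by_condition,
        label_breakdown=breakdown,
        confusion=confusion,
        n_static_samples=int(on_static.sum()),
        n_moving_samples=int(on_moving.sum()),
    )


def target_interval_gaze_speed(
    segments: Sequence[Segment],
    ray: RayCastSeries,
    speeds: SpeedSeries,
    events: EventLog,
    exclusion: float = 20.0,
) -> pd.DataFrame:
    """Mean gaze speed in each trial's longest on-target intersaccadic interval.

    Per trial, intersaccadic intervals whose modal ray-cast label is the
    cued disk are candidates; the longest one contributes the mean gaze
    speed over its usable samples, excluding samples whose eye speed
    exceeds ``exclusion`` deg/s (guarding against catch-up saccade
    residue).  Trials without such an interval get NaN.
    """
    cues = events.of_kind("cue_onset")
    cue_t = cues["t"].to_numpy(dtype=float)
    info = cues.set_index("trial_id")
    cued = {tid: disk_label(20.0 if r["condition_eccentricity"] == "peripheral"
                            else 6.0, int(r["cued_disk_index"]))
            for tid, r in info.iterrows()}

    intervals: dict = {}
    for s in segments:
        if s.interval_id is None or s.label == "noise":
            continue
        key = s.interval_id
        cur = intervals.setdefault(key, [s.i_start, s.i_end, s.t_start, s.t_end])
        cur[0] = min(cur[0], s.i_start)
        cur[1] = max(cur[1], s.i_end)
        cur[2] = min(cur[2], s.t_start)
        cur[3] = max(cur[3], s.t_end)

    best: dict = {}
    for key, (i0, i1, ts, te) in intervals.items():
        k = int(np.searchsorted(cue_t, ts, side="right")) - 1
        if k < 0:
            continue
        tid = int(cues["trial_id"].iloc[k])
        lab = pd.Series(ray.label[i0:i1 + 1]).mode()
        if lab.empty or lab.iloc[0] != cued[tid]:
            continue
        dur = te - ts
        if tid not in best or dur > best[tid][0]:
            best[tid] = (dur, i0, i1)

    rows = []
    for tid, r in info.iterrows():
        row = {"trial_id": int(tid), "condition_motion": r["condition_motion"],
               "condition_eccentricity": r["condition_eccentricity"],
               "mean_gaze_speed": np.nan, "interval_duration": np.nan}
        if tid in best:
            dur, i0, i1 = best[tid]
            sl = slice(i0, i1 + 1)
            ok = speeds.usable[sl] & (speeds.eye_speed[sl] <= exclusion)
            if ok.any():
                row["mean_gaze_speed"] = float(np.mean(speeds.gaze_speed[sl][ok]))
                row["interval_duration"] = dur
        rows.append(row)
    return pd.DataFrame(rows)


def main_sequence_stats(groups: dict) -> pd.DataFrame:
    """Mean amplitude, skewness, and (non-excess) kurtosis per group.

    Kurtosis is the standardized fourth central moment (normal = 3).
    Groups with fewer than 3 saccades or zero variance are flagged
    ``degenerate`` with NaN moments.
    """
    rows = []
    for name, amps in groups.items():
        a = np.asarray(amps, dtype=float)
        degenerate = len(a) < 3 or np.std(a) == 0
        rows.append({
            "group": name,
            "n": len(a),
            "mean_amplitude": float(np.mean(a)) if len(a) else np.nan,
            "skewness": np.nan if degenerate else float(sps.skew(a)),
            "kurtosis": np.nan if degenerate else float(
                sps.kurtosis(a, fisher=False)),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def reaction_times(
    segments: Sequence[Segment],
    events: EventLog,
    ray: RayCastSeries,
    min_amplitude: float = 3.0,
) -> pd.DataFrame:
    """Per-trial saccadic RT, button RT, and disengagement time (seconds).

    Saccadic RT: onset of the first included saccade (amplitude >=
    ``min_amplitude``) after cue onset, minus cue onset.  Button RT: first
    response between target onset and the next trial's cue, minus target
    onset.  Disengagement: first post-target time the ray-cast label leaves
    the cued disk, minus target onset.
    """
    cues = events.of_kind("cue_onset")
    targets = events.of_kind("target_onset").set_index("trial_id")["t"]
    responses = events.of_kind("response")
    cue_t = cues["t"].to_numpy(dtype=float)

    sacc_onsets = np.array([s.t_start for s in segments
                            if s.label == "saccade"
                            and (s.amplitude or 0) >= min_amplitude])
    sacc_onsets.sort()

    rows = []
    for k, row in cues.iterrows():
        tid = int(row["trial_id"])
        c = float(row["t"])
        next_cue = float(cue_t[k + 1]) if k + 1 < len(cue_t) else np.inf
        tgt = float(targets.loc[tid]) if tid in targets.index else np.nan

        srt = np.nan
        j = np.searchsorted(sacc_onsets, c, side="right")
        if j < len(sacc_onsets) and sacc_onsets[j] < next_cue:
            srt = float(sacc_onsets[j] - c)

        brt = np.nan
        if np.isfinite(tgt):
            resp = responses[(responses["t"] >= tgt)
                             & (responses["t"] < next_cue)]
            if len(resp):  # only first responses are analyzed
                brt = float(resp["t"].iloc[0] - tgt)

        dis = np.nan
        if np.isfinite(tgt):
            cued = disk_label(
                20.0 if row["condition_eccentricity"] == "peripheral" else 6.0,
                int(row["cued_disk_index"]))
            sel = (ray.t > tgt) & (ray.t < next_cue)
            idx = np.flatnonzero(sel)
            if idx.size:
                on = ray.label[idx] == cued
                prev_on = ray.label[idx - 1] == cued
                leave = np.flatnonzero(~on & prev_on)
                if leave.size:
                    dis = float(ray.t[idx[leave[0]]] - tgt)
        rows.append({"trial_id": tid, "saccadic_rt": srt,
                     "button_rt": brt, "disengagement": dis})
    return pd.DataFrame(rows)


def valid_sample_fraction(rec: GazeRecording) -> float:
    """Fraction of samples flagged valid."""
    if rec.n == 0:
        raise ValueError("recording is empty")
    return float(np.mean(rec.valid.astype(bool)))


def classification_agreement(
    segments: Sequence[Segment],
    truth,
    n: Optional[int] = None,
) -> dict:
    """Per-sample agreement between predicted segments and ground truth.

    Compared over samples the classifier deems usable (not noise);
    ``unclassified`` predictions count as disagreement.  Returns the
    overall fraction and a per-truth-label breakdown.
    """
    if n is None:
        n = truth.n
    pred = segment_labels_per_sample(segments, n)
    usable = pred != "noise"
    tl = np.asarray(truth.label)
    match = (pred == tl) & usable
    per_label = {}
    for lab in np.unique(tl[usable]):
        sel = usable & (tl == lab)
        per_label[str(lab)] = float(match[sel].sum() / sel.sum())
    return {
        "overall": float(match[usable].sum() / usable.sum()),
        "per_truth_label": per_label,
        "n_compared": int(usable.sum()),
    }


def saccade_recovery(
    segments: Sequence[Segment],
    truth,
    usable: Optional[np.ndarray] = None,
    min_amplitude: float = 3.0,
    min_overlap: float = 0.5,
    min_duration_samples: int = 3,
) -> dict:
    """Fraction of detectable injected saccades (amplitude >= 3 deg) recovered.

    A truth saccade is *detectable* when its window retains a contiguous
    usable run of at least ``min_duration_samples`` — dropout masking
    excludes samples from classification outright, so a saccade it
    obliterates is not presented to the classifier at all.  A detectable
    saccade counts as recovered when a predicted ``saccade`` segment covers
    at least ``min_overlap`` of the window's usable samples.
    """
    det = [(s.i_start, s.i_end) for s in segments if s.label == "saccade"]
    tsac = truth.saccades
    tsac = tsac[(tsac["amplitude"] >= min_amplitude) & (tsac["i_start"] >= 0)]
    n_eligible = 0
    n_found = 0
    for _, row in tsac.iterrows():
        a0, a1 = int(row["i_start"]), int(row["i_end"])
        if usable is not None:
            u = usable[a0:a1 + 1]
            run, best_run = 0, 0
            for flag in u:
                run = run + 1 if flag else 0
                best_run = max(best_run, run)
            if best_run < min_duration_samples:
                continue
            n_usable = int(u.sum())
        else:
            n_usable = a1 - a0 + 1
        n_eligible += 1
        need = min_overlap * n_usable
        for b0, b1 in det:
            ov = min(a1, b1) - max(a0, b0) + 1
            if ov >= need:
                n_found += 1
                break
    return {"n_true": int(len(tsac)), "n_eligible": n_eligible,
            "n_recovered": n_found,
            "fraction": n_found / n_eligible if n_eligible else np.nan}
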