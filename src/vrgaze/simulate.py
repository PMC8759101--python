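"""Synthetic gaze sessions with per-sample ground truth.

The generator emulates the cued visual-discrimination paradigm at 120 Hz:
each trial fixates the recentering cross, makes a cue-triggered saccade
(latency ~ N(200, 30) ms) to the cued disk, fixates (static trials) or
pursues (dynamic trials, gain-scaled to the disk's instantaneous angular
velocity) the disk, presses a button after target onset, and returns to the
cross.  Saccades obey a saturating main sequence
``v_peak = vmax * (1 - exp(-A / c))`` with a raised-cosine velocity
profile.  Peripheral gaze shifts recruit the head: a minimum-jerk head
rotation carrying a fraction of the shift, timed so head speed peaks
``head_lag`` after the eye's peak, with the eye counter-rotating (VOR) at
``vor_gain`` once gaze is on target.  Fixational noise is white angular
jitter low-passed at 20 Hz; dropout arrives in geometric bursts (mean 3
samples) to mimic blinks.

Ground-truth labels are *kinematic*: the label the threshold taxonomy
assigns to the noise-free generated speeds.  Slow pursuit whose gaze speed
sits below the low-gaze threshold is therefore truth-labeled fixation —
which is exactly what makes the paradigm's slow-pursuit classification
failure measurable against the separately carried behavioural phase and
foveated-object columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter
from scipy.spatial.transform import Rotation

from . import kinematics
from .classify import ThresholdSet, scale_threshold
from .io import EventLog, GazeRecording, EVENT_COLUMNS
from .paradigm import (TrialSpec, TrialSchedule, WorldLayout, disk_label,
                       disk_position)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_trial",
    "simulate_session",
    "sample_saccade_profile",
    "main_sequence_peak_velocity",
    "add_dropout",
]


@dataclass
class SimulationParams:
    """Knobs of the synthetic session generator.

    Defaults are the study conditions: 120 Hz sampling, ~200 ms saccade
    latency, 6% sample dropout (94% valid), head speed peaking ~200 ms
    after the eye, and pursuit/VOR gains slightly below unity.
    """

    sample_rate: float = 120.0        # Hz
    saccade_latency: float = 0.200    # s, mean
    saccade_latency_sd: float = 0.030
    main_sequence_vmax: float = 500.0  # deg/s
    main_sequence_c: float = 14.0      # deg
    fixation_noise_sd: float = 2.0     # deg/s, filtered eye speed in fixation
    pursuit_gain: float = 0.95
    vor_gain: float = 0.95
    head_contribution: float = 0.3     # fraction of eccentric gaze shifts
    head_lag: float = 0.200            # s, head peak after eye peak
    dropout_rate: float = 0.06
    seed: int = 0
    # secondary timing constants (artifact-defined, see docs/methods.md)
    button_rt: float = 0.450           # s, mean
    button_rt_sd: float = 0.080
    pre_cue: float = 1.0               # s of cross fixation before each cue
    iti_range: tuple = (5.4, 7.4)      # s between cue onsets (mean 6.4)
    dynamic_return_distance: float = 12.5  # m; disk range triggering return
    catch_up_threshold: float = 1.5    # deg of pursuit lag before a catch-up
    head_move_duration: float = 0.5    # s, minimum-jerk outbound head move
    head_return_duration: float = 0.45
    truth_thresholds: ThresholdSet = field(default_factory=ThresholdSet)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("pursuit_gain", "vor_gain", "head_contribution",
                     "dropout_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-sample intent of the generator, aligned 1:1 with the samples."""

    t: np.ndarray
    label: np.ndarray     # kinematic truth label (Segment label set)
    phase: np.ndarray     # behavioural phase (cross / saccade / on_target ...)
    obj: np.ndarray       # scripted foveated object ('' during saccades)
    saccades: pd.DataFrame  # scripted saccades: i_start, i_end, amplitude, ...

    @property
    def n(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "label": self.label,
                             "phase": self.phase, "object": self.obj})


def main_sequence_peak_velocity(amplitude, params: SimulationParams):
    """Main-sequence peak velocity: vmax * (1 - exp(-A / c)), deg/s."""
    a = np.asarray(amplitude, dtype=float)
    return params.main_sequence_vmax * (1.0 - np.exp(-a / params.main_sequence_c))


def _saccade_duration(amplitude: float, params: SimulationParams) -> float:
    """Raised-cosine profile duration so the waveform integrates to A."""
    vp = float(main_sequence_peak_velocity(amplitude, params))
    return 2.0 * amplitude / vp


def sample_saccade_profile(amplitude: float, params: SimulationParams) -> np.ndarray:
    """Velocity waveform (deg/s) of a saccade, sampled at ``sample_rate``.

    Raised cosine: smooth, unimodal, peak ``vmax * (1 - exp(-A/c))``, and
    its continuous integral equals the amplitude exactly.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    dur = _saccade_duration(amplitude, params)
    vp = float(main_sequence_peak_velocity(amplitude, params))
    n = int(math.ceil(dur * params.sample_rate)) + 1
    tt = np.linspace(0.0, dur, n)
    return 0.5 * vp * (1.0 - np.cos(2.0 * np.pi * tt / dur))


def _scurve(u: np.ndarray) -> np.ndarray:
    """Normalized raised-cosine displacement: s(0)=0, s(1)=1."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _minjerk(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _dir_from_azel(az: np.ndarray, el: np.ndarray) -> np.ndarray:
    """Left-handed y-up z-forward unit vector from azimuth/elevation (rad)."""
    return np.stack([np.sin(az) * np.cos(el), np.sin(el),
                     np.cos(az) * np.cos(el)], axis=-1)


def _azel_from_dir(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    az = np.arctan2(d[..., 0], d[..., 2])
    el = np.arcsin(np.clip(d[..., 1], -1.0, 1.0))
    return az, el


def _head_rotation(az: np.ndarray, el: np.ndarray) -> Rotation:
    """Yaw-then-pitch rotation mapping (0,0,1) to the (az, el) direction."""
    angles = np.stack([az, -el], axis=-1)
    return Rotation.from_euler("YX", angles)


def _quat_wxyz(r: Rotation) -> np.ndarray:
    q = r.as_quat()  # (x, y, z, w)
    return np.concatenate([q[..., 3:], q[..., :3]], axis=-1)


def add_dropout(valid: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Invalidate contiguous bursts (geometric length, mean 3) at ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    valid = np.asarray(valid, dtype=bool).copy()
    n = len(valid)
    if rate == 0.0 or n == 0:
        return valid
    if rate == 1.0:
        valid[:] = False
        return valid
    mean_len = 3.0
    n_bursts = int(round(rate * n / mean_len))
    starts = rng.integers(0, n, size=n_bursts)
    lengths = rng.geometric(1.0 / mean_len, size=n_bursts)
    for s, ln in zip(starts, lengths):
        valid[s:s + ln] = False
    return valid


# --- fixational noise calibration -------------------------------------------
_NOISE_FACTOR_CACHE: dict = {}


def _jitter_speed_factor(fs: float) -> float:
    """Mean median-filtered eye speed (deg/s) per degree of jitter SD.

    Measured once on a long synthetic fixation trace with unit-SD jitter;
    used to convert the target fixation speed into a positional jitter SD.
    """
    key = round(fs, 3)
    if key not in _NOISE_FACTOR_CACHE:
        rng = np.random.default_rng(987654321)
        n = 12000
        t = np.arange(n) / fs
        az, el = _filtered_jitter(n, 1.0, fs, rng)
        dirs = _dir_from_azel(np.radians(az), np.radians(el))
        sp = kinematics.median_filter(kinematics.angular_speed(dirs, t), 5)
        _NOISE_FACTOR_CACHE[key] = float(np.mean(sp))
    return _NOISE_FACTOR_CACHE[key]


def _filtered_jitter(n: int, sd_deg: float, fs: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """White angular jitter low-passed at 20 Hz, per axis, degrees."""
    b, a = butter(2, 20.0, btype="low", fs=fs)
    az = lfilter(b, a, rng.standard_normal(n))
    el = lfilter(b, a, rng.standard_normal(n))
    # renormalize so the filtered series has the requested SD
    scale_az = sd_deg / max(np.std(az), 1e-12)
    scale_el = sd_deg / max(np.std(el), 1e-12)
    return az * scale_az, el * scale_el


# --- trial synthesis ---------------------------------------------------------

def simulate_trial(
    trial: TrialSpec,
    layout: WorldLayout,
    params: SimulationParams,
    rng: np.random.Generator,
    span: Optional[float] = None,
    t0: float = 0.0,
    z0: float = 0.0,
) -> tuple[dict, list[dict], GroundTruth]:
    """Generate one trial's samples, events, and ground truth.

    The trial block covers ``span`` seconds starting at ``t0`` with the cue
    at ``t0 + pre_cue``; the block begins and ends fixating the cross with
    the head at rest, so blocks concatenate seamlessly.  ``z0`` is the
    observer's forward position at block start (advances at 5 m/s within
    dynamic trials).
    """
    fs = params.sample_rate
    dt = 1.0 / fs
    if span is None:
        span = float(np.mean(params.iti_range))
    n = int(round(span * fs))
    t_rel = np.arange(n) * dt
    tc = t_rel - params.pre_cue            # time since cue
    ecc = trial.eccentricity_dva
    dynamic = trial.motion == "dynamic"

    def target_azel(t_since_cue):
        p = np.array([disk_position(layout, ecc, trial.cued_disk_index,
                                    trial.cue_distance, float(ts), trial.motion)
                      for ts in np.atleast_1d(t_since_cue)])
        d = p / np.linalg.norm(p, axis=-1, keepdims=True)
        az, el = _azel_from_dir(d)
        return az, el

    # --- key times (relative to cue) ---
    lat = float(np.clip(rng.normal(params.saccade_latency,
                                   params.saccade_latency_sd), 0.10, 0.40))
    az_t, el_t = target_azel(lat)
    tgt0 = _dir_from_azel(az_t, el_t)[0]
    amp1 = math.degrees(math.acos(np.clip(tgt0[2], -1.0, 1.0)))
    d1 = _saccade_duration(amp1, params)
    land = lat + d1
    resp = trial.soa + float(np.clip(rng.normal(params.button_rt,
                                                params.button_rt_sd), 0.20, 1.0))
    if dynamic:
        ro = (trial.cue_distance - params.dynamic_return_distance) \
            / layout.observer_speed
        ro = max(ro, resp + 0.2)
    else:
        ro = resp + 0.2
    ro = min(ro, span - params.pre_cue - 1.0)  # finish before the next cue

    # --- gaze path (world az/el, radians) ---
    gaze_az = np.zeros(n)
    gaze_el = np.zeros(n)
    phase = np.full(n, "cross", dtype=object)
    obj = np.full(n, "cross", dtype=object)
    target_label = disk_label(ecc, trial.cued_disk_index)
    catch_ups: list[tuple[int, int, float]] = []

    m_sac1 = (tc >= lat) & (tc < land)
    m_on = (tc >= land) & (tc < ro)
    az_land, el_land = target_azel(land)
    az_land, el_land = float(az_land[0]), float(el_land[0])
    if m_sac1.any():
        u = (tc[m_sac1] - lat) / d1
        s = _scurve(u)
        gaze_az[m_sac1] = s * az_land
        gaze_el[m_sac1] = s * el_land
        phase[m_sac1] = "saccade"
        obj[m_sac1] = ""
    on_idx = np.flatnonzero(m_on)
    if on_idx.size:
        if dynamic:
            taz, tel = target_azel(tc[on_idx])
            dphi = np.hypot(np.diff(taz) * np.cos(tel[:-1]), np.diff(tel))
            phi = np.concatenate([[0.0], np.cumsum(dphi)])
            lag = (1.0 - params.pursuit_gain) * phi
            rec_cum = np.zeros_like(phi)
            while True:
                deficit = lag - rec_cum
                over = deficit > math.radians(params.catch_up_threshold)
                if not over.any():
                    break
                k = int(np.argmax(over))
                amp = float(deficit[k])
                ncu = 4
                j = min(k + ncu, len(phi))
                ramp = _scurve(np.arange(1, j - k + 1) / (j - k))
                rec_cum[k:j] += ramp * amp
                rec_cum[j:] += amp
                catch_ups.append((int(on_idx[0]) + k, int(on_idx[0]) + j - 1,
                                  math.degrees(amp)))
            p = params.pursuit_gain * phi + rec_cum
            gaze_az[on_idx] = np.interp(p, phi, taz)
            gaze_el[on_idx] = np.interp(p, phi, tel)
        else:
            gaze_az[on_idx] = az_land
            gaze_el[on_idx] = el_land
        phase[on_idx] = "on_target"
        obj[on_idx] = target_label

    # --- head path: minimum-jerk contribution for peripheral targets ---
    head_az = np.zeros(n)
    head_el = np.zeros(n)
    hc = params.head_contribution if trial.eccentricity == "peripheral" else 0.0
    if hc > 0:
        h_az, h_el = hc * az_land, hc * el_land
        dh = params.head_move_duration
        th0 = lat + d1 / 2.0 + params.head_lag - dh / 2.0
        u = _minjerk((tc - th0) / dh)
        head_az += u * h_az
        head_el += u * h_el
        # return move starts with the return saccade
        ur = _minjerk((tc - ro) / params.head_return_duration)
        head_az -= ur * h_az
        head_el -= ur * h_el

    # --- imperfect VOR: gaze leaks a fraction of head motion while holding ---
    leak = 1.0 - params.vor_gain
    if hc > 0 and leak > 0:
        for mask in (m_on, tc >= ro):
            idx = np.flatnonzero(mask)
            if idx.size:
                gaze_az[idx] += leak * (head_az[idx] - head_az[idx[0]])
                gaze_el[idx] += leak * (head_el[idx] - head_el[idx[0]])

    # --- return saccade (from the leaked gaze position at ro) ---
    i_ro = int(np.searchsorted(tc, ro))
    if i_ro < n:
        az0, el0 = gaze_az[max(i_ro - 1, 0)], gaze_el[max(i_ro - 1, 0)]
        g0 = _dir_from_azel(np.array(az0), np.array(el0))
        amp2 = math.degrees(math.acos(np.clip(g0[2], -1.0, 1.0)))
        amp2 = max(amp2, 0.5)
        d2 = _saccade_duration(amp2, params)
        m_sac2 = (tc >= ro) & (tc < ro + d2)
        m_post = tc >= ro + d2
        u = (tc[m_sac2] - ro) / d2
        s = _scurve(u)
        gaze_az[m_sac2] = az0 * (1.0 - s)
        gaze_el[m_sac2] = el0 * (1.0 - s)
        phase[m_sac2] = "saccade"
        obj[m_sac2] = ""
        gaze_az[m_post] = 0.0
        gaze_el[m_post] = 0.0
        phase[m_post] = "cross"
        obj[m_post] = "cross"
        # VOR leak while refixating the cross during the head's return move
        if hc > 0 and leak > 0:
            idx = np.flatnonzero(m_post)
            if idx.size:
                gaze_az[idx] += leak * (head_az[idx] - head_az[idx[0]])
                gaze_el[idx] += leak * (head_el[idx] - head_el[idx[0]])
    else:  # pragma: no cover - spans always leave room for the return
        m_sac2 = np.zeros(n, dtype=bool)
        amp2, d2 = 0.0, 0.0

    # --- assemble sample streams ---
    gaze_dir = _dir_from_azel(gaze_az, gaze_el)
    head_rot = _head_rotation(head_az, head_el)
    eye_dir = head_rot.inv().apply(gaze_dir)
    head_quat = _quat_wxyz(head_rot)
    pos = np.zeros((n, 3))
    pos[:, 2] = z0 + (layout.observer_speed * t_rel if dynamic else 0.0)

    t_abs = t0 + t_rel
    sacc_rows = [
        {"i_start": int(np.flatnonzero(m_sac1)[0]) if m_sac1.any() else -1,
         "i_end": int(np.flatnonzero(m_sac1)[-1]) if m_sac1.any() else -1,
         "t_onset": t0 + params.pre_cue + lat, "amplitude": amp1,
         "kind": "primary", "trial_id": trial.trial_id},
        {"i_start": int(np.flatnonzero(m_sac2)[0]) if m_sac2.any() else -1,
         "i_end": int(np.flatnonzero(m_sac2)[-1]) if m_sac2.any() else -1,
         "t_onset": t0 + params.pre_cue + ro, "amplitude": amp2,
         "kind": "return", "trial_id": trial.trial_id},
    ]
    for (i0c, i1c, ampc) in catch_ups:
        sacc_rows.append({"i_start": i0c, "i_end": i1c,
                          "t_onset": t_abs[i0c], "amplitude": ampc,
                          "kind": "catch_up", "trial_id": trial.trial_id})
    saccades = pd.DataFrame(sacc_rows)

    samples = {"t": t_abs, "eye_dir": eye_dir, "head_quat": head_quat,
               "head_pos": pos, "gaze_dir": gaze_dir}
    truth_label = _truth_labels(t_abs, eye_dir, head_quat, gaze_dir,
                                saccades, params)
    truth = GroundTruth(t=t_abs, label=truth_label, phase=phase, obj=obj,
                        saccades=saccades)

    base = {"trial_id": trial.trial_id, "condition_motion": trial.motion,
            "condition_eccentricity": trial.eccentricity,
            "cue_distance_m": trial.cue_distance,
            "target_dir": trial.target_dir, "response_side": "",
            "cued_disk_index": trial.cued_disk_index,
            "distractor_disk_index": trial.distractor_disk_index}
    events = [
        {**base, "t": t0, "kind": "trial_start"},
        {**base, "t": t0 + params.pre_cue, "kind": "cue_onset"},
        {**base, "t": t0 + params.pre_cue + trial.soa, "kind": "target_onset"},
        {**base, "t": t0 + params.pre_cue + resp, "kind": "response",
         "response_side": trial.target_dir},
    ]
    return samples, events, truth


def _truth_labels(
    t: np.ndarray,
    eye_dir: np.ndarray,
    head_quat: np.ndarray,
    gaze_dir: np.ndarray,
    saccades: pd.DataFrame,
    params: SimulationParams,
) -> np.ndarray:
    """Kinematic truth: threshold taxonomy applied to noise-free speeds."""
    thr = params.truth_thresholds
    eye_sp = kinematics.angular_speed(eye_dir, t)
    head_sp = kinematics.head_angular_speed(head_quat, t)
    gaze_sp = kinematics.angular_speed(gaze_dir, t)

    n = len(t)
    in_sacc = np.zeros(n, dtype=bool)
    sacc_amp = np.zeros(n)
    for _, row in saccades.iterrows():
        if row["i_start"] < 0:
            continue
        sl = slice(int(row["i_start"]), int(row["i_end"]) + 1)
        in_sacc[sl] = True
        sacc_amp[sl] = row["amplitude"]

    scaled_sacc = scale_threshold(head_sp, thr.theta_saccade,
                                  thr.scaling_denominator)
    low_gaze = scale_threshold(head_sp, thr.theta_lowgaze,
                               thr.scaling_denominator)
    low_eye = scale_threshold(head_sp, thr.theta_loweye,
                              thr.scaling_denominator)
    is_sacc = in_sacc & (eye_sp > scaled_sacc)
    tree = np.select(
        [gaze_sp <= low_gaze, eye_sp <= low_eye, head_sp <= thr.theta_head],
        [np.where(head_sp <= thr.theta_head, "fixation", "vor"),
         "head_pursuit", "smooth_pursuit"],
        default="sp_vor",
    ).astype(object)
    labels = np.where(
        is_sacc, np.where(sacc_amp >= 3.0, "saccade", "excluded_saccade"),
        tree).astype(object)
    return labels


def simulate_session(
    schedule: TrialSchedule,
    layout: WorldLayout,
    params: SimulationParams,
) -> tuple[GazeRecording, EventLog, GroundTruth]:
    """Simulate a full session: deterministic per seed, ~120 Hz samples.

    Trials are concatenated with cue-to-cue spacing uniform on
    ``iti_range`` (mean 6.4 s); fixational jitter and burst dropout are
    applied to the assembled eye stream.
    """
    fs = params.sample_rate
    rng = np.random.default_rng(params.seed)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    dropout_rng = np.random.default_rng(rng.integers(2**31))

    blocks, all_events, truths = [], [], []
    t0, z0 = 0.0, 0.0
    for trial in schedule.trials:
        iti = float(rng.uniform(*params.iti_range))
        n_span = int(round(iti * fs))
        span = n_span / fs
        samples, events, truth = simulate_trial(
            trial, layout, params, rng, span=span, t0=t0, z0=z0)
        blocks.append(samples)
        all_events.extend(events)
        truths.append(truth)
        if trial.motion == "dynamic":
            z0 = float(samples["head_pos"][-1, 2] + layout.observer_speed / fs)
        t0 += span

    t = np.concatenate([b["t"] for b in blocks])
    eye = np.concatenate([b["eye_dir"] for b in blocks])
    quat = np.concatenate([b["head_quat"] for b in blocks])
    pos = np.concatenate([b["head_pos"] for b in blocks])
    n = len(t)

    # fixational noise on the eye-in-head direction
    if params.fixation_noise_sd > 0:
        factor = _jitter_speed_factor(fs)
        sd_deg = params.fixation_noise_sd / factor
        jaz, jel = _filtered_jitter(n, sd_deg, fs, noise_rng)
        az, el = _azel_from_dir(eye)
        eye = _dir_from_azel(az + np.radians(jaz), el + np.radians(jel))

    valid = add_dropout(np.ones(n, dtype=bool), params.dropout_rate,
                        dropout_rng)

    offset = 0
    sacc_frames = []
    for b, tr in zip(blocks, truths):
        df = tr.saccades.copy()
        keep = df["i_start"] >= 0
        df.loc[keep, "i_start"] += offset
        df.loc[keep, "i_end"] += offset
        sacc_frames.append(df[keep])
        offset += len(b["t"])
    truth = GroundTruth(
        t=t,
        label=np.concatenate([tr.label for tr in truths]),
        phase=np.concatenate([tr.phase for tr in truths]),
        obj=np.concatenate([tr.obj for tr in truths]),
        saccades=pd.concat(sacc_frames, ignore_index=True),
    )

    rec = GazeRecording(t=t, eye_dir=eye, head_quat=quat, head_pos=pos,
                        valid=valid, pupil_mm=np.full(n, 3.5)).validate()
    ev = pd.DataFrame(all_events)
    for c in EVENT_COLUMNS:
        if c not in ev.columns:
            ev[c] = np.nan
    log = EventLog(events=ev[EVENT_COLUMNS]).validate()
    return rec, log, truth
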