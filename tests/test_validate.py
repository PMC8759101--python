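import numpy as np
import pandas as pd
import pytest

from vrgaze import validate as vd
from vrgaze.classify import Segment
from vrgaze.io import EventLog
from vrgaze.kinematics import SpeedSeries
from vrgaze.paradigm import disk_label

FS = 120.0


class TestRaycast:
    OBJECTS = [
        ("cross", np.array([0.0, 0.0, 11.0]), 0.09),
        (disk_label(20, 0), np.array([4.73, 0.0, 13.0]), 0.5),
    ]

    def test_gaze_at_disk_center(self):
        d = np.array([4.73, 0.0, 13.0])
        label, dist = vd.raycast(np.zeros(3), d / np.linalg.norm(d),
                                 self.OBJECTS)
        assert label == disk_label(20, 0)
        assert dist == pytest.approx(np.linalg.norm(d) - 0.5, abs=1e-6)

    def test_small_offset_still_hits_disk(self):
        # 1.5 deg off a 1 m disk at ~13.8 m: the radius subtends ~2.1 deg
        center = np.array([4.73, 0.0, 13.0])
        c = center / np.linalg.norm(center)
        axis = np.array([0.0, 1.0, 0.0])
        ang = np.radians(1.5)
        d = c * np.cos(ang) + np.cross(axis, c) * np.sin(ang)
        label, _ = vd.raycast(np.zeros(3), d, self.OBJECTS)
        assert label == disk_label(20, 0)

    def test_far_from_everything_is_background(self):
        d = np.array([np.sin(np.radians(60)), 0.0, np.cos(np.radians(60))])
        label, dist = vd.raycast(np.zeros(3), d, self.OBJECTS)
        assert label == "background"
        assert np.isnan(dist)

    def test_direction_magnitude_irrelevant(self):
        d = np.array([4.73, 0.0, 13.0])
        l1, _ = vd.raycast(np.zeros(3), d, self.OBJECTS)
        l2, _ = vd.raycast(np.zeros(3), d * 7.3, self.OBJECTS)
        assert l1 == l2

    def test_nearest_hit_wins(self):
        objs = [("far", np.array([0.0, 0.0, 20.0]), 1.0),
                ("near", np.array([0.0, 0.0, 5.0]), 1.0)]
        label, _ = vd.raycast(np.zeros(3), np.array([0.0, 0.0, 1.0]), objs)
        assert label == "near"


def _tiny_trial_fixture():
    """One static trial, gaze on the cued disk for a 1 s interval."""
    n = 600
    t = np.arange(n) / FS
    cue_t, target_t = 1.0, 2.0
    cued = disk_label(20, 2)
    ray_label = np.full(n, "cross", dtype=object)
    on = (t >= 1.4) & (t < 2.4)  # 1 s on-target interval
    ray_label[on] = cued
    ray = vd.RayCastSeries(t=t, label=ray_label, hit_distance=np.zeros(n))

    gaze = np.full(n, 9.0)
    eye = np.full(n, 5.0)
    burst = slice(200, 203)  # catch-up burst: excluded from the average
    eye[burst] = 50.0
    gaze[burst] = 40.0
    speeds = SpeedSeries(t=t, eye_speed=eye, head_speed=np.zeros(n),
                         gaze_speed=gaze, usable=np.ones(n, dtype=bool))

    i_on = np.flatnonzero(on)
    segments = [Segment(int(i_on[0]), int(i_on[-1]), 1.4, 2.4, "fixation",
                        interval_id=0)]
    base = {"trial_id": 0, "condition_motion": "static",
            "condition_eccentricity": "peripheral", "cue_distance_m": 13.0,
            "target_dir": "left", "response_side": "", "cued_disk_index": 2,
            "distractor_disk_index": 6}
    ev = pd.DataFrame([
        {**base, "t": 0.0, "kind": "trial_start"},
        {**base, "t": cue_t, "kind": "cue_onset"},
        {**base, "t": target_t, "kind": "target_onset"},
        {**base, "t": 2.45, "kind": "response", "response_side": "left"},
    ])
    return ray, speeds, segments, EventLog(ev).validate()


class TestTargetIntervalGazeSpeed:
    def test_constant_gaze_interval_returns_its_speed(self):
        ray, speeds, segments, events = _tiny_trial_fixture()
        speeds.eye_speed[:] = 5.0
        speeds.gaze_speed[:] = 9.0
        out = vd.target_interval_gaze_speed(segments, ray, speeds, events)
        assert out.loc[0, "mean_gaze_speed"] == pytest.approx(9.0)

    def test_catch_up_burst_excluded_from_mean(self):
        ray, speeds, segments, events = _tiny_trial_fixture()
        out = vd.target_interval_gaze_speed(segments, ray, speeds, events)
        # burst samples (eye 50 > 20 deg/s) do not contaminate the average
        assert out.loc[0, "mean_gaze_speed"] == pytest.approx(9.0)

    def test_never_on_target_gives_nan(self):
        ray, speeds, segments, events = _tiny_trial_fixture()
        ray.label[:] = "cross"
        out = vd.target_interval_gaze_speed(segments, ray, speeds, events)
        assert np.isnan(out.loc[0, "mean_gaze_speed"])

    def test_longest_on_target_interval_selected(self):
        ray, speeds, segments, events = _tiny_trial_fixture()
        # add a second, shorter on-target interval with different speed
        i2 = np.arange(320, 350)
        ray.label[i2] = disk_label(20, 2)
        speeds.gaze_speed[:] = 9.0
        speeds.eye_speed[:] = 5.0
        speeds.gaze_speeds = None
        segments = segments + [Segment(320, 349, float(ray.t[319]),
                                       float(ray.t[349]), "fixation",
                                       interval_id=1)]
        speeds.gaze_speed[i2] = 20.0
        out = vd.target_interval_gaze_speed(segments, ray, speeds, events)
        assert out.loc[0, "mean_gaze_speed"] == pytest.approx(9.0)


class TestReactionTimes:
    def test_spec_cases(self):
        ray, speeds, segments, events = _tiny_trial_fixture()
        segs = [Segment(0, 5, 1.18, 1.23, "saccade", amplitude=10.0,
                        peak_velocity=300.0)]
        out = vd.reaction_times(segs, events, ray)
        assert out.loc[0, "saccadic_rt"] == pytest.approx(0.18, abs=1 / FS)
        assert out.loc[0, "button_rt"] == pytest.approx(0.45, abs=1e-9)
        # disengagement: ray leaves the cued disk at t = 2.4
        assert out.loc[0, "disengagement"] == pytest.approx(0.4, abs=1.5 / FS)

    def test_small_saccades_not_counted_for_rt(self):
        ray, _, _, events = _tiny_trial_fixture()
        segs = [Segment(0, 5, 1.18, 1.23, "saccade", amplitude=2.0,
                        peak_velocity=300.0),
                Segment(10, 15, 1.30, 1.35, "saccade", amplitude=8.0,
                        peak_velocity=300.0)]
        out = vd.reaction_times(segs, events, ray)
        assert out.loc[0, "saccadic_rt"] == pytest.approx(0.30, abs=1e-9)

    def test_late_response_excluded_and_first_response_used(self):
        ray, _, segments, events = _tiny_trial_fixture()
        df = events.events
        base = df.iloc[0].to_dict()
        extra = pd.DataFrame([
            {**base, "t": 2.60, "kind": "response", "response_side": "right"},
            {**base, "t": 7.4, "kind": "trial_start", "trial_id": 1},
            {**base, "t": 8.4, "kind": "cue_onset", "trial_id": 1},
            {**base, "t": 9.0, "kind": "target_onset", "trial_id": 1},
            # trial 0's very late press, 2 ms after trial 1's cue
            {**base, "t": 8.402, "kind": "response", "trial_id": 0},
        ]).sort_values("t")
        log = EventLog(pd.concat([df, extra], ignore_index=True)
                       .sort_values("t").reset_index(drop=True)).validate()
        out = vd.reaction_times(segments, log, ray)
        assert out.loc[0, "button_rt"] == pytest.approx(0.45)  # first response
        assert np.isnan(out.loc[1, "button_rt"])  # response after next cue


class TestMainSequenceStats:
    def test_symmetric_sample_near_zero_skew(self):
        rng = np.random.default_rng(0)
        out = vd.main_sequence_stats({"g": rng.uniform(5, 15, 5000)})
        assert abs(out.loc[0, "skewness"]) < 0.1

    def test_normal_sample_kurtosis_converges_to_3(self):
        rng = np.random.default_rng(1)
        out = vd.main_sequence_stats({"g": rng.normal(10, 2, 200_000)})
        assert out.loc[0, "kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_constant_amplitudes_flagged_degenerate(self):
        out = vd.main_sequence_stats({"g": np.full(10, 5.0)})
        assert bool(out.loc[0, "degenerate"])
        assert np.isnan(out.loc[0, "skewness"])


class TestValidSampleFraction:
    def test_fractions(self):
        from test_io import make_recording
        rec = make_recording(100, invalid_frac=0)
        assert vd.valid_sample_fraction(rec) == 1.0
        rec.valid[:6] = False
        assert vd.valid_sample_fraction(rec) == pytest.approx(0.94)

    def test_empty_rejected(self):
        from vrgaze.io import GazeRecording
        rec = GazeRecording(t=np.array([]), eye_dir=np.zeros((0, 3)),
                            head_quat=np.zeros((0, 4)),
                            head_pos=np.zeros((0, 3)),
                            valid=np.array([], dtype=bool))
        with pytest.raises(ValueError):
            vd.valid_sample_fraction(rec)


class TestPursuitValidationOnSessions:
    def test_static_fixation_rarely_called_pursuit(self, noiseless_session):
        s = noiseless_session
        ray = vd.raycast_series(s["rec"], s["events"],
                                __import__("vrgaze").paradigm.WorldLayout())
        rep = vd.pursuit_validation(s["segments"], ray, s["events"],
                                    truth=s["truth"])
        assert rep.pct_pursuit_on_static is not None
        assert rep.pct_pursuit_on_static < 2.0

    def test_report_consistent_with_breakdown_counts(self, small_session):
        from vrgaze.paradigm import WorldLayout
        sess = small_session
        ray = vd.raycast_series(sess["rec"], sess["events"], WorldLayout())
        rep = vd.pursuit_validation(sess["segments"], ray, sess["events"],
                                    truth=sess["truth"])
        counts = rep.label_breakdown["on_static"]
        total = sum(counts.values())
        pursuit = sum(v for k, v in counts.items() if k in vd.PURSUIT_LABELS)
        assert rep.pct_pursuit_on_static == pytest.approx(
            100.0 * pursuit / total, abs=1e-9)
        assert total == rep.n_static_samples
        # confusion table covers every usable (non-noise) sample
        n_confusion = sum(sum(r.values()) for r in rep.confusion.values())
        n_usable = sum(seg.n_samples for seg in sess["segments"]
                       if seg.label != "noise")
        assert n_confusion == n_usable

    def test_absent_category_reports_none(self):
        ray, speeds, segments, events = _tiny_trial_fixture()
        rep = vd.pursuit_validation(segments, ray, events)
        assert rep.pct_pursuit_on_moving is None  # no dynamic trials

    def test_disengagement_matches_scripted_departure(self, noiseless_session):
        from vrgaze.paradigm import WorldLayout
        s = noiseless_session
        ray = vd.raycast_series(s["rec"], s["events"], WorldLayout())
        rts = vd.reaction_times(s["segments"], s["events"], ray)
        targets = s["events"].of_kind("target_onset").set_index("trial_id")["t"]
        ret = s["truth"].saccades.query("kind == 'return'").set_index("trial_id")
        got, expected = [], []
        for tid, row in rts.set_index("trial_id").iterrows():
            if np.isnan(row["disengagement"]) or tid not in ret.index:
                continue
            got.append(row["disengagement"])
            expected.append(float(ret.loc[tid, "t_onset"]) - targets.loc[tid])
        got, expected = np.array(got), np.array(expected)
        assert len(got) > 50
        # departure is detected within the return saccade's flight time
        assert np.all(got >= expected - 1.5 / FS)
        assert np.median(np.abs(got - expected)) < 0.06
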