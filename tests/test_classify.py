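import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrgaze import classify as clf
from vrgaze.classify import Segment, ThresholdSet
from vrgaze.kinematics import SpeedSeries

FS = 120.0


def make_speeds(eye, head=None, gaze=None, usable=None):
    eye = np.asarray(eye, dtype=float)
    n = len(eye)
    return SpeedSeries(
        t=np.arange(n) / FS,
        eye_speed=eye,
        head_speed=np.zeros(n) if head is None else np.asarray(head, float),
        gaze_speed=eye.copy() if gaze is None else np.asarray(gaze, float),
        usable=np.ones(n, dtype=bool) if usable is None else np.asarray(usable),
    )


def brute_force_saccades(speeds, thr, min_duration=0.020):
    """Independent oracle: explicit per-sample scan for supra-threshold runs."""
    t = speeds.t
    dt_nom = float(np.median(np.diff(t)))
    hot = []
    for i in range(len(t)):
        scaled = (1.0 + speeds.head_speed[i] / thr.scaling_denominator) \
            * thr.theta_saccade
        hot.append(bool(speeds.usable[i]) and speeds.eye_speed[i] > scaled)
    found = []
    i = 0
    while i < len(hot):
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(hot) and hot[j + 1]:
            j += 1
        t_start = t[i - 1] if i > 0 else t[i] - dt_nom
        if t[j] - t_start >= min_duration - 1e-12:
            found.append((i, j))
        i = j + 1
    return found


class TestScaleThreshold:
    @pytest.mark.parametrize("v_head,base,expected", [
        (0.0, 35.0, 35.0),
        (60.0, 35.0, 70.0),
        (30.0, 10.0, 15.0),
    ])
    def test_printed_formula(self, v_head, base, expected):
        assert clf.scale_threshold(v_head, base) == pytest.approx(expected)

    def test_negative_head_speed_rejected(self):
        with pytest.raises(ValueError):
            clf.scale_threshold(-1.0, 35.0)

    def test_strictly_increasing_in_head_speed(self):
        v = np.linspace(0, 100, 50)
        out = clf.scale_threshold(v, 35.0)
        assert np.all(np.diff(out) > 0)


class TestDetectSaccades:
    def test_quiet_trace_no_saccades(self):
        sp = make_speeds(np.full(100, 5.0))
        assert clf.detect_saccades(sp, ThresholdSet()) == []

    def test_four_sample_burst_detected(self):
        eye = np.full(60, 5.0)
        eye[20:24] = 50.0
        segs = clf.detect_saccades(make_speeds(eye), ThresholdSet())
        assert len(segs) == 1
        assert (segs[0].i_start, segs[0].i_end) == (20, 23)

    def test_two_sample_burst_too_short(self):
        eye = np.full(60, 5.0)
        eye[20:22] = 50.0
        assert clf.detect_saccades(make_speeds(eye), ThresholdSet()) == []

    def test_fast_head_raises_threshold_above_eye(self):
        # eye at 50 deg/s everywhere, head at 60 -> scaled threshold 70
        sp = make_speeds(np.full(100, 50.0), head=np.full(100, 60.0))
        assert clf.detect_saccades(sp, ThresholdSet()) == []

    def test_unusable_samples_break_runs(self):
        eye = np.full(60, 50.0)
        usable = np.ones(60, dtype=bool)
        usable[30] = False
        segs = clf.detect_saccades(make_speeds(eye, usable=usable),
                                   ThresholdSet())
        assert [(s.i_start, s.i_end) for s in segs] == [(0, 29), (31, 59)]

    def test_empty_series(self):
        assert clf.detect_saccades(make_speeds(np.array([])),
                                   ThresholdSet()) == []

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 400))
        eye = np.abs(rng.normal(10, 8, n))
        spikes = rng.random(n) < 0.15
        eye[spikes] += rng.uniform(20, 150, spikes.sum())
        head = np.abs(rng.normal(5, 10, n))
        usable = rng.random(n) > 0.05
        sp = make_speeds(eye, head=head, usable=usable)
        thr = ThresholdSet()
        got = [(s.i_start, s.i_end) for s in clf.detect_saccades(sp, thr)]
        assert got == brute_force_saccades(sp, thr)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_raising_head_speed_never_adds_saccade_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        eye = np.abs(rng.normal(20, 25, n))
        head = np.abs(rng.normal(5, 5, n))
        thr = ThresholdSet()
        def n_samples(h):
            segs = clf.detect_saccades(make_speeds(eye, head=h), thr)
            return sum(s.n_samples for s in segs)
        assert n_samples(head + 30.0) <= n_samples(head)


class TestFilterSaccades:
    def _sacc(self, amp, peak):
        return Segment(0, 5, 0.0, 0.05, "saccade", amplitude=amp,
                       peak_velocity=peak)

    @pytest.mark.parametrize("amp,peak,expected", [
        (2.9, 400.0, "excluded_saccade"),
        (17.0, 400.0, "saccade"),
        (10.0, 1050.0, "excluded_saccade"),
        (3.0, 999.9, "saccade"),
        (10.0, 1000.0, "excluded_saccade"),
    ])
    def test_exclusion_boundaries(self, amp, peak, expected):
        out = clf.filter_saccades([self._sacc(amp, peak)])
        assert out[0].label == expected

    def test_nothing_deleted(self):
        segs = [self._sacc(1.0, 100.0), self._sacc(10.0, 300.0)]
        assert len(clf.filter_saccades(segs)) == 2

    def test_metrics_required(self):
        with pytest.raises(ValueError):
            clf.filter_saccades([Segment(0, 5, 0.0, 0.05, "saccade")])


class TestPartitionIntersaccadic:
    def test_430ms_interval_tiles_100_100_100_130(self):
        # 430 ms of usable samples (52 samples at 120 Hz spans ~433 ms)
        n = 52
        sp = make_speeds(np.full(n, 2.0))
        epochs = clf.partition_intersaccadic([], sp)
        widths = [round(e.duration, 4) for e in epochs]
        assert len(widths) == 4
        assert widths[:3] == [0.1, 0.1, 0.1]
        assert 0.1 < widths[3] <= 0.14
        assert epochs[-1].i_end == n - 1

    def test_100ms_interval_single_epoch(self):
        sp = make_speeds(np.full(12, 2.0))
        epochs = clf.partition_intersaccadic([], sp)
        assert len(epochs) == 1
        assert epochs[0].duration == pytest.approx(0.1)

    def test_40ms_isolated_interval_unclassified(self):
        sp = make_speeds(np.full(5, 2.0))  # ~42 ms < 50 ms
        epochs = clf.partition_intersaccadic([], sp)
        assert [e.label for e in epochs] == ["unclassified"]

    def test_70ms_interval_single_short_epoch(self):
        sp = make_speeds(np.full(8, 2.0))  # ~67 ms in (50, 100)
        epochs = clf.partition_intersaccadic([], sp)
        assert len(epochs) == 1
        assert epochs[0].label == "epoch"

    def test_saccade_samples_not_tiled(self):
        n = 40
        sp = make_speeds(np.full(n, 2.0))
        sacc = [Segment(10, 19, sp.t[9], sp.t[19], "saccade")]
        epochs = clf.partition_intersaccadic(sacc, sp)
        covered = set()
        for e in epochs:
            covered.update(range(e.i_start, e.i_end + 1))
        assert covered.isdisjoint(range(10, 20))
        assert covered == set(range(0, 10)) | set(range(20, 40))


class TestClassifyEpoch:
    @pytest.mark.parametrize("gaze,eye,head,expected", [
        (0.0, 0.0, 0.0, "fixation"),
        (3.0, 12.0, 12.0, "vor"),            # scaled low gaze 12 >= 3, head > 7
        (25.0, 25.0, 1.0, "smooth_pursuit"),
        (25.0, 2.0, 25.0, "head_pursuit"),
        (25.0, 18.0, 12.0, "sp_vor"),
    ])
    def test_flow_chart_cases(self, gaze, eye, head, expected):
        assert clf.classify_epoch(gaze, eye, head, ThresholdSet()) == expected

    def test_threshold_equality_resolves_to_slower_branch(self):
        thr = ThresholdSet()
        assert clf.classify_epoch(10.0, 0.0, 0.0, thr) == "fixation"
        assert clf.classify_epoch(10.0, 0.0, 7.0, thr) == "fixation"
        assert clf.classify_epoch(15.0, 10.0, 0.0, thr) == "head_pursuit"
        assert clf.classify_epoch(15.0, 12.0, 7.0, thr) == "smooth_pursuit"


class TestClassifyRecording:
    def test_short_recording_rejected(self, cfg):
        from vrgaze.io import GazeRecording
        rec = GazeRecording(
            t=np.array([0.0]), eye_dir=np.array([[0.0, 0, 1]]),
            head_quat=np.array([[1.0, 0, 0, 0]]), head_pos=np.zeros((1, 3)),
            valid=np.array([True]))
        with pytest.raises(ValueError):
            clf.classify_recording(rec, cfg)

    def test_segments_tile_recording(self, small_session):
        segs = small_session["segments"]
        n = small_session["rec"].n
        seen = np.zeros(n, dtype=int)
        for s in segs:
            assert s.i_start <= s.i_end
            assert s.t_start < s.t_end
            seen[s.i_start:s.i_end + 1] += 1
        assert np.all(seen == 1)

    def test_excluded_saccades_stay_excluded(self, full_session):
        labels = {s.label for s in full_session["segments"]}
        assert "excluded_saccade" in labels  # catch-up-sized events exist
        for s in full_session["segments"]:
            if s.label == "excluded_saccade":
                assert s.amplitude < 3.0 or s.peak_velocity >= 1000.0
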