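"""Velocity computation, adaptive thresholding and event segmentation."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeflow import (
    EventDetectionParams,
    GazeStream,
    InsufficientDataError,
    VelocitySeries,
    angular_velocity,
    classify_events,
    detect_events,
    gaze_trial_metrics,
    saccade_threshold,
)

DT = 1000.0 / 90.0  # nominal sample period, ms


def make_stream(dirs, valid=None, dt_ms=DT):
    dirs = np.asarray(dirs, dtype=float)
    n = len(dirs)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeStream(t_ms=np.arange(n) * dt_ms, dirs=dirs, valid=valid)


def series_from_speeds(speeds, valid=None, dt_ms=DT):
    """Build a VelocitySeries directly from interval speeds."""
    speeds = np.asarray(speeds, dtype=float)
    n = len(speeds)
    edges = np.arange(n + 1) * dt_ms
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return VelocitySeries(
        t_mid_ms=0.5 * (edges[:-1] + edges[1:]),
        v_deg_s=speeds,
        valid=np.asarray(valid, dtype=bool),
        t_edges_ms=edges,
    )


def rot_about_z(deg):
    r = np.radians(deg)
    return np.array([np.cos(r), np.sin(r), 0.0])


class TestAngularVelocity:
    def test_constant_direction_gives_zero_speed(self):
        v = angular_velocity(make_stream([[1, 0, 0]] * 10))
        assert np.allclose(v.v_deg_s, 0.0)

    def test_one_degree_per_sample_at_90hz(self):
        s = make_stream([rot_about_z(0), rot_about_z(1.0)])
        v = angular_velocity(s)
        assert v.v_deg_s[0] == pytest.approx(1.0 / (DT / 1000.0), rel=1e-9)

    def test_orthogonal_vectors_one_second_apart(self):
        s = GazeStream(
            t_ms=np.array([0.0, 1000.0]),
            dirs=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
            valid=np.ones(2, dtype=bool),
        )
        assert angular_velocity(s).v_deg_s[0] == pytest.approx(90.0)

    def test_interval_touching_invalid_sample_is_invalid_at_edge(self):
        # leading invalid sample cannot be bridged: no valid left bound
        valid = np.array([False, True, True, True])
        v = angular_velocity(make_stream([[1, 0, 0]] * 4, valid=valid))
        assert not v.valid[0] and v.valid[1:].all()

    def test_short_gap_is_bridged_with_constant_speed(self):
        dirs = [rot_about_z(0), rot_about_z(1), [0, 0, 0], rot_about_z(3), rot_about_z(4)]
        valid = np.array([True, True, False, True, True])
        v = angular_velocity(make_stream(dirs, valid=valid), gap_bridge_ms=75.0)
        assert v.valid.all()
        # bridged speed spread uniformly: 2 deg over 2 sample periods
        assert v.v_deg_s[1] == pytest.approx(v.v_deg_s[2], rel=1e-9)

    def test_long_gap_stays_invalid(self):
        n_gap = 10  # ~111 ms > 75 ms bridge limit
        dirs = [rot_about_z(0)] * 3 + [[0, 0, 0]] * n_gap + [rot_about_z(5)] * 3
        valid = np.array([True] * 3 + [False] * n_gap + [True] * 3)
        v = angular_velocity(make_stream(dirs, valid=valid))
        assert not v.valid[3 : 3 + n_gap - 1].any()

    def test_fewer_than_two_valid_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            angular_velocity(make_stream([[1, 0, 0]] * 3, valid=np.array([True, False, False])))


class TestSaccadeThreshold:
    @pytest.mark.parametrize(
        "speeds, expected",
        [
            ([10.0] * 7, 50.0),
            ([0, 10, 20, 30, 40], 100.0),
            ([1, 2, 3, 4], 12.5),  # even-length median = mean of central pair
        ],
    )
    def test_five_times_median(self, speeds, expected):
        assert saccade_threshold(series_from_speeds(speeds)) == pytest.approx(expected)

    def test_no_valid_intervals_raises(self):
        vs = series_from_speeds([1.0, 2.0], valid=[False, False])
        with pytest.raises(InsufficientDataError):
            saccade_threshold(vs)


def brute_force_segment(vs, threshold, saccade_max_ms=50.0, fixation_min_ms=100.0):
    """Independent oracle: enumerate every maximal run via groupby over
    per-interval labels and apply the duration gates literally."""
    labels = [
        "invalid" if not ok else ("above" if v > threshold else "below")
        for v, ok in zip(vs.v_deg_s, vs.valid)
    ]
    out = []
    pos = 0
    for label, grp in itertools.groupby(labels):
        length = len(list(grp))
        i, j = pos, pos + length - 1
        pos += length
        if label == "invalid":
            continue
        onset, offset = vs.t_edges_ms[i], vs.t_edges_ms[j + 1]
        dur = offset - onset
        if label == "above":
            kind = "saccade" if dur <= saccade_max_ms else "unclassified"
        else:
            kind = "fixation" if dur > fixation_min_ms else "unclassified"
        out.append((kind, onset, offset))
    return out


class TestClassifyEvents:
    def test_single_long_below_run_is_one_fixation(self):
        vs = series_from_speeds([10.0] * 30)  # ~333 ms below threshold
        events = classify_events(vs, threshold=50.0)
        assert [e.kind for e in events] == ["fixation"]
        assert events[0].duration_ms == pytest.approx(30 * DT)

    def test_short_above_run_between_fixations_is_a_saccade(self):
        speeds = [10.0] * 20 + [200.0] * 3 + [10.0] * 20  # 3 intervals ≈ 33 ms
        events = classify_events(series_from_speeds(speeds), threshold=50.0)
        assert [e.kind for e in events] == ["fixation", "saccade", "fixation"]

    def test_duration_gates_leave_middling_runs_unclassified(self):
        # 6 above-threshold intervals ≈ 67 ms: too long for a saccade
        ev = classify_events(series_from_speeds([200.0] * 6), threshold=50.0)
        assert [e.kind for e in ev] == ["unclassified"]
        # 8 below-threshold intervals ≈ 89 ms: too short for a fixation
        ev = classify_events(series_from_speeds([10.0] * 8), threshold=50.0)
        assert [e.kind for e in ev] == ["unclassified"]

    def test_speed_exactly_at_threshold_counts_as_below(self):
        ev = classify_events(series_from_speeds([50.0] * 12), threshold=50.0)
        assert [e.kind for e in ev] == ["fixation"]

    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 300))
            speeds = rng.lognormal(2.5, 1.2, n)
            valid = rng.random(n) > 0.05
            vs = series_from_speeds(speeds, valid=valid)
            thr = 5 * np.median(speeds)
            got = [(e.kind, e.onset_ms, e.offset_ms) for e in classify_events(vs, thr)]
            assert got == brute_force_segment(vs, thr)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        speeds=st.lists(st.floats(0.0, 500.0), min_size=1, max_size=120),
        c=st.floats(0.1, 10.0),
    )
    def test_threshold_scale_equivariance(self, speeds, c):
        """Multiplying all speeds by c scales the threshold by c and leaves
        the event partition unchanged."""
        vs = series_from_speeds(speeds)
        thr = 5 * float(np.median(speeds))
        if thr <= 0:
            return
        vs_scaled = series_from_speeds([s * c for s in speeds])
        ev1 = classify_events(vs, thr)
        ev2 = classify_events(vs_scaled, thr * c)
        assert [(e.kind, e.onset_ms, e.offset_ms) for e in ev1] == [
            (e.kind, e.onset_ms, e.offset_ms) for e in ev2
        ]

    def test_events_plus_gaps_tile_the_trial(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            speeds = rng.lognormal(2.5, 1.0, n)
            valid = rng.random(n) > 0.1
            vs = series_from_speeds(speeds, valid=valid)
            events = classify_events(vs, 5 * float(np.median(speeds)))
            covered = sum(e.duration_ms for e in events)
            gap = np.sum(~vs.valid) * DT
            total = vs.t_edges_ms[-1] - vs.t_edges_ms[0]
            assert covered + gap == pytest.approx(total, abs=1e-6)
            # disjoint and ordered
            for a, b in zip(events, events[1:]):
                assert a.offset_ms <= b.onset_ms


class TestGazeTrialMetrics:
    def test_formulas_on_two_fixations(self):
        events = classify_events(series_from_speeds([1.0] * 27 + [99.0] * 3 + [1.0] * 45), 50.0)
        fix = [e for e in events if e.kind == "fixation"]
        assert len(fix) == 2
        m = gaze_trial_metrics(events, duration_ms=3600.0, ref_duration_ms=3600.0)
        durs = [e.duration_ms for e in fix]
        assert m.n_fixations_norm == pytest.approx(2.0)
        assert m.mean_fix_dur_ms == pytest.approx(np.mean(durs))
        assert m.search_rate == pytest.approx(2.0 / sum(durs))

    def test_normalization_halves_counts_for_double_duration(self):
        from gazeflow.types import GazeEvent

        events = [GazeEvent("fixation", i * 400.0, i * 400.0 + 300.0) for i in range(4)]
        m = gaze_trial_metrics(events, duration_ms=7200.0, ref_duration_ms=3600.0)
        assert m.n_fixations_norm == pytest.approx(2.0)

    def test_no_fixations_gives_nan_duration_metrics(self):
        m = gaze_trial_metrics([], duration_ms=1000.0)
        assert m.n_fixations_norm == 0.0
        assert np.isnan(m.mean_fix_dur_ms) and np.isnan(m.search_rate)


class TestDetectEventsEndToEnd:
    def test_smoothing_switch_runs(self, small_study):
        key = next(iter(small_study.gaze))
        ev_raw, _ = detect_events(small_study.gaze[key])
        ev_sm, _ = detect_events(small_study.gaze[key], EventDetectionParams(smoothing=True))
        assert ev_raw and ev_sm

    def test_recovers_generated_fixation_count(self, small_study):
        gt = small_study.ground_truth
        key = next(iter(small_study.gaze))
        events, _ = detect_events(small_study.gaze[key])
        n_true = sum(1 for e in gt.events_for(key) if e.kind == "fixation")
        n_det = sum(1 for e in events if e.kind == "fixation")
        assert n_det == n_true
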