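"""Kinematics derivation, trial matching, time warping, and modulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossarea import behavior
from crossarea.containers import (EmptySelectionError, KinematicTrace,
                                  SessionRecord, TrialTable)


def make_trace(wrist, digits=None, fps=50.0):
    F = wrist.shape[0]
    if digits is None:
        digits = np.zeros((F, 4, 2))
    return KinematicTrace(frame_times=np.arange(F) / fps,
                          wrist_points=wrist, digit_points=digits)


def make_table(reach_rel, retract_rel, touch=None, success=None, attempts=None):
    n = len(reach_rel)
    touch = np.arange(10.0, 10.0 * (n + 1), 10.0)[:n] if touch is None else np.asarray(touch)
    df = pd.DataFrame({
        "reach_onset": touch + np.asarray(reach_rel),
        "touch": touch,
        "retract": touch + np.asarray(retract_rel),
        "success": True if success is None else success,
        "attempted": True,
        "grasp_attempts": 1 if attempts is None else attempts,
    })
    return TrialTable(df)


class TestWristSpeed:
    def test_stationary_zero(self):
        w = np.zeros((20, 3, 2))
        assert np.nanmax(behavior.wrist_speed(make_trace(w))) == 0.0

    def test_pythagorean_three_four_five(self):
        F = 10
        w = np.zeros((F, 3, 2))
        w[:, :, 0] = 3.0 * np.arange(F)[:, None]
        w[:, :, 1] = 4.0 * np.arange(F)[:, None]
        sp = behavior.wrist_speed(make_trace(w), smooth=False)
        np.testing.assert_allclose(sp[1:], 5.0)

    def test_redundancy_mean_over_available(self):
        F = 10
        w = np.zeros((F, 3, 2))
        w[:, 0, 0] = np.arange(F)        # speed 1
        w[:, 1, 0] = 2.0 * np.arange(F)  # speed 2
        w[:, 2, :] = np.nan              # lost point
        sp = behavior.wrist_speed(make_trace(w), smooth=False)
        np.testing.assert_allclose(sp[1:], 1.5)

    def test_all_points_missing_frame_is_nan(self):
        w = np.zeros((10, 3, 2))
        w[5] = np.nan
        sp = behavior.wrist_speed(make_trace(w), smooth=False)
        assert np.isnan(sp[5])

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(30, 3, 2)).cumsum(axis=0)
        s1 = behavior.wrist_speed(make_trace(w))
        s2 = behavior.wrist_speed(make_trace(w + np.array([100.0, -50.0])))
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestHandAperture:
    def test_distance_oracle(self):
        F = 5
        d = np.zeros((F, 4, 2))
        d[:, 2:, :] = [6.0, 8.0]  # both index points at (6,8); thumb at origin
        ap, _ = behavior.hand_aperture(make_trace(np.zeros((F, 3, 2)), d))
        np.testing.assert_allclose(ap, 10.0)

    def test_coincident_points_zero(self):
        d = np.ones((5, 4, 2)) * 7.0
        ap, _ = behavior.hand_aperture(make_trace(np.zeros((5, 3, 2)), d))
        np.testing.assert_allclose(ap, 0.0)

    def test_monotone_opening_peaks_at_last_pretouch_frame(self):
        F = 200
        d = np.zeros((F, 4, 2))
        d[:, 2:, 0] = np.linspace(0, 50, F)[:, None]  # opens monotonically
        trace = make_trace(np.zeros((F, 3, 2)), d)
        table = make_table([-0.5], [0.3], touch=[2.0])
        _, max_t = behavior.hand_aperture(trace, table)
        frames = trace.frame_times
        pretouch = frames[(frames >= 1.5) & (frames <= 2.0)]
        assert max_t[0] == pretouch[-1]


class TestSelectMatchedTrials:
    def test_identical_durations_all_kept(self):
        table = make_table([-0.4] * 5, [0.3] * 5)
        idx = behavior.select_matched_trials(table)
        assert idx.tolist() == [0, 1, 2, 3, 4]

    def test_duration_fixture_excludes_outlier(self):
        # reach-to-touch durations 0.30, 0.35, 0.52 vs median 0.35, tol 0.1
        table = make_table([-0.30, -0.35, -0.52], [0.3] * 3)
        idx = behavior.select_matched_trials(table, tolerance=0.1)
        assert idx.tolist() == [0, 1]

    def test_multi_attempt_trials_excluded(self):
        table = make_table([-0.4] * 4, [0.3] * 4, attempts=[1, 2, 1, 3])
        idx = behavior.select_matched_trials(table)
        assert idx.tolist() == [0, 2]

    def test_stable_under_reapplication_with_same_medians(self):
        rng = np.random.default_rng(1)
        table = make_table(-0.4 + rng.uniform(-0.2, 0.2, 30),
                           0.3 + rng.uniform(-0.2, 0.2, 30))
        ok = table.success
        med = (float(np.median(table.reach_to_touch()[ok])),
               float(np.median(table.touch_to_retract()[ok])))
        idx1 = behavior.select_matched_trials(table, medians=med)
        sub = table.subset(idx1)
        idx2 = behavior.select_matched_trials(sub, medians=med)
        assert idx2.tolist() == list(range(len(sub.df)))

    def test_empty_selection_raises(self):
        table = make_table([-0.4], [0.3], success=[False])
        with pytest.raises(EmptySelectionError):
            behavior.select_matched_trials(table)


class TestTimeWarp:
    grid = np.arange(-1.0, 1.0, 0.02) + 0.01   # bin centers, s rel. touch

    def test_identity_bitwise_at_medians(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=self.grid.size)
        out = behavior.time_warp(x, self.grid, 0.45, 0.30, (0.45, 0.30))
        assert np.array_equal(out, x)

    def test_touch_anchor_preserved(self):
        grid = np.arange(-50, 51) * 0.02    # contains t = 0 exactly
        rng = np.random.default_rng(3)
        x = rng.normal(size=grid.size)
        k0 = int(np.where(grid == 0.0)[0][0])
        for rt, tr in [(0.3, 0.2), (0.6, 0.5), (0.45, 0.3)]:
            out = behavior.time_warp(x, grid, rt, tr, (0.45, 0.30))
            # t=0 is a fixed point of the warp for every trial
            assert out[k0] == x[k0]

    def test_double_speed_reach_matches_interp_oracle(self):
        x = np.sin(2 * np.pi * self.grid)
        rt, medians = 0.8, (0.4, 0.3)
        out = behavior.time_warp(x, self.grid, rt, 0.3, medians)
        # oracle: warped time of source sample u is u*(0.4/0.8) on the
        # pre-touch segment; resample by direct linear interpolation
        w = np.where(self.grid < -rt, self.grid + (rt - 0.4),
                     np.where(self.grid < 0, self.grid * 0.5, self.grid))
        expect = np.interp(self.grid, w, x)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_out_of_order_events_rejected(self):
        with pytest.raises(ValueError):
            behavior.time_warp(np.zeros(10), np.linspace(-1, 1, 10),
                               -0.1, 0.3, (0.4, 0.3))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(rt=st.floats(0.2, 0.9), tr=st.floats(0.1, 0.9))
    def test_idempotent_on_already_warped(self, rt, tr):
        rng = np.random.default_rng(4)
        x = rng.normal(size=self.grid.size)
        med = (0.45, 0.30)
        once = behavior.time_warp(x, self.grid, rt, tr, med)
        # a warped trace is at the median timing; warping again is identity
        twice = behavior.time_warp(once, self.grid, med[0], med[1], med)
        np.testing.assert_array_equal(once, twice)


class TestEpochModulation:
    time_ms = np.arange(-1000.0, 1000.0, 20.0) + 10.0
    events = {"reach_onset": -450.0, "touch": 0.0, "retract": 300.0}

    def test_flat_trace_unmodulated(self):
        res = behavior.epoch_modulation(np.zeros(self.time_ms.size),
                                        self.time_ms, self.events)
        assert not res.task_modulated[0]
        assert all(m[0] == 0.0 for m in res.magnitude.values())

    def test_grasp_bump_detected_only_in_grasp(self):
        trace = np.zeros(self.time_ms.size)
        sel = (self.time_ms >= -50) & (self.time_ms <= 150)
        trace[sel] = 1.5
        res = behavior.epoch_modulation(trace, self.time_ms, self.events)
        assert res.task_modulated[0]
        assert res.epoch_modulated["grasp"][0]
        assert res.magnitude["grasp"][0] == pytest.approx(1.5)
        assert not res.epoch_modulated["pre_reach"][0]
        assert not res.epoch_modulated["reach"][0]
        assert not res.epoch_modulated["retract"][0]

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(5)
        trace = rng.normal(size=(self.time_ms.size, 3))
        r1 = behavior.epoch_modulation(trace, self.time_ms, self.events)
        r2 = behavior.epoch_modulation(-trace, self.time_ms, self.events)
        for k in r1.magnitude:
            np.testing.assert_array_equal(r1.magnitude[k], r2.magnitude[k])

    def test_epoch_outside_support_skipped(self):
        short_t = np.arange(-100.0, 200.0, 20.0)
        with pytest.warns(UserWarning, match="skipped"):
            res = behavior.epoch_modulation(np.zeros(short_t.size), short_t,
                                            self.events)
        assert "pre_reach" not in res.magnitude


class TestClassifySessions:
    def rec(self, day, n=20):
        return SessionRecord(animal_id="a", day_post_lesion=day, n_rewarded=n)

    def test_baseline_equal_durations_late(self):
        base = np.full(30, 0.8)
        recs = behavior.classify_sessions([self.rec(5, n=3)], [np.full(20, 0.8)],
                                          base)
        assert recs[0].phase == "Late"
        assert recs[0].normalized_r2g_duration == pytest.approx(1.0)

    def test_few_rewarded_not_early(self):
        base = np.full(30, 0.8)
        recs = behavior.classify_sessions(
            [self.rec(1, n=4), self.rec(2, n=10), self.rec(3, n=10),
             self.rec(4, n=10)],
            [np.full(10, 1.6)] * 4, base)
        assert recs[0].phase == "Other"     # only 4 rewarded: not Early
        assert recs[1].phase == "Early"
        assert recs[2].phase == "Early"     # first two qualifying sessions
        assert recs[3].phase == "Other"     # 2x baseline: rank-sum rejects

    def test_doubled_durations_not_late(self):
        rng = np.random.default_rng(6)
        base = 0.8 + 0.05 * rng.standard_normal(40)
        recs = behavior.classify_sessions([self.rec(9, n=2)],
                                          [2.0 * base[:20]], base)
        assert recs[0].phase == "Other"
        assert recs[0].normalized_r2g_duration == pytest.approx(2.0, rel=0.1)

    def test_missing_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            behavior.classify_sessions([self.rec(1)], [np.ones(5)], np.array([]))


class TestGapInterpolation:
    def test_short_gap_filled_long_gap_kept(self):
        x = np.arange(20.0)
        x[[5, 6]] = np.nan          # short gap
        x[10:15] = np.nan           # 5-frame gap: too long
        out = behavior.interpolate_short_gaps(x, max_gap=3)
        np.testing.assert_allclose(out[[5, 6]], [5.0, 6.0])
        assert np.isnan(out[10:15]).all()
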