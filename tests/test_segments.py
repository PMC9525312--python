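"""Changepoint segmentation and stationary/processive classification."""

import numpy as np
import pandas as pd
import pytest

from septatrack.segments import (analyze_track, classify_segment,
                                 population_summary, segment_stats,
                                 segment_track, Segment)


def _ut(t, s):
    return pd.DataFrame({"t": t, "s": s})


class TestSegmentTrack:
    def test_single_line_not_split(self):
        t = np.arange(30.0)
        assert segment_track(_ut(t, 3.0 * t + 1.0)) == [(0, 30)]

    def test_noiseless_changepoint_found_within_one_frame(self):
        t = np.arange(40.0)
        s = np.where(t < 20, 0.0, 9.0 * (t - 19))
        ranges = segment_track(_ut(t, s))
        assert len(ranges) == 2
        assert abs(ranges[0][1] - 20) <= 1

    def test_short_track_unsegmented_and_unclassifiable(self):
        t = np.arange(5.0)
        ranges = segment_track(_ut(t, t))
        assert ranges == [(0, 5)]
        segs = analyze_track(_ut(t, t))
        assert segs[0].label == "unclassified"


class TestSegmentStats:
    def test_perfect_line_r_zero_p_one(self):
        t = np.arange(20.0)
        v, r, p = segment_stats(9.0 * t + 2.0, t, seed=0)
        assert v == pytest.approx(9.0)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_processive_example_r_near_quarter(self):
        # 15 frames at 9 nm/s with 30 nm noise: R ~ sigma/(v*T) ~ 0.24
        rng = np.random.default_rng(42)
        t = np.arange(15.0)
        rs = []
        for _ in range(200):
            s = 9.0 * t + rng.normal(0, 30, 15)
            rs.append(segment_stats(s, t, seed=1)[1])
        assert np.median(rs) == pytest.approx(30 / 126, abs=0.08)
        assert np.median(rs) <= 0.4

    def test_zero_displacement_is_stationary_by_construction(self):
        t = np.arange(10.0)
        s = np.zeros(10)
        v, r, p = segment_stats(s, t, seed=0)
        assert np.isinf(r) and p == 0.0
        assert classify_segment((v, r, p)) == "stationary"

    def test_pure_noise_classified_stationary_in_90pct_of_replicates(self):
        rng = np.random.default_rng(2024)
        t = np.arange(15.0)
        n_stat = 0
        n_rep = 1000
        for _ in range(n_rep):
            s = rng.normal(0, 30, 15)
            st = segment_stats(s, t, rng=rng)
            n_stat += classify_segment(st) == "stationary"
        assert n_stat / n_rep >= 0.90

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        t = np.arange(12.0)
        s = 4.0 * t + rng.normal(0, 25, 12)
        assert segment_stats(s, t, seed=5) == segment_stats(s, t, seed=5)


class TestClassify:
    @pytest.mark.parametrize("r,p,label", [
        (0.4, 0.5, "processive"),   # inclusive thresholds
        (0.41, 0.9, "stationary"),
        (0.1, 0.4, "stationary"),
        (0.1, 0.9, "processive"),
    ])
    def test_threshold_table(self, r, p, label):
        assert classify_segment((1.0, r, p)) == label


class TestInvariances:
    def _stats(self, s, t):
        return segment_stats(s, t, seed=9)

    def test_time_reversal_and_sign_flip(self):
        rng = np.random.default_rng(8)
        t = np.arange(20.0)
        s = 7.0 * t + rng.normal(0, 20, 20)
        v0, r0, p0 = self._stats(s, t)
        vf, rf, pf = self._stats(-s, t)
        assert vf == pytest.approx(-v0)
        assert rf == pytest.approx(r0)
        assert pf == pytest.approx(p0)
        vr, rr, pr = self._stats(s[::-1].copy(), t)
        assert vr == pytest.approx(-v0)
        assert rr == pytest.approx(r0, rel=1e-9)

    def test_scale_invariance_of_r_p_and_label(self):
        rng = np.random.default_rng(3)
        t = np.arange(18.0)
        s = 5.0 * t + rng.normal(0, 30, 18)
        v0, r0, p0 = self._stats(s, t)
        v1, r1, p1 = self._stats(1000.0 * s, t)
        assert r1 == pytest.approx(r0)
        assert p1 == pytest.approx(p0)
        assert classify_segment((v0, r0, p0)) == classify_segment((v1, r1, p1))

    def test_zero_noise_labels_match_ground_truth(self):
        t = np.arange(12.0)
        proc = segment_stats(9.0 * t, t, seed=0)
        stat = segment_stats(np.full(12, 5.0), t, seed=0)
        assert classify_segment(proc) == "processive"
        assert classify_segment(stat) == "stationary"


class TestSummary:
    def _seg(self, label, v=9.0, n=15):
        return Segment(0, 0, n, n, v, 0.1, 0.9, label, float(n - 1),
                       abs(v) * (n - 1))

    def test_all_processive_percentages(self):
        out = population_summary([self._seg("processive")] * 4)
        assert out["pct_processive"] == 100.0
        assert out["pct_stationary"] == 0.0

    def test_dwell_time_is_n_minus_one_times_interval(self):
        out = population_summary([self._seg("stationary", v=0.0, n=28)])
        assert out["dwell_times"] == [27.0]

    def test_unclassified_excluded_from_percentages(self):
        segs = [self._seg("processive"), self._seg("stationary"),
                Segment(0, 0, 4, 4, np.nan, np.nan, np.nan, "unclassified",
                        3.0, np.nan)]
        out = population_summary(segs)
        assert out["n_segments"] == 2
        assert out["pct_stationary"] == 50.0

    def test_empty_input_gives_empty_summary(self):
        out = population_summary([])
        assert out["n_segments"] == 0 and out["speeds"] == []


def test_analyze_track_manual_breakpoints_bypass_search():
    t = np.arange(30.0)
    s = np.where(t < 15, 0.0, 9.0 * (t - 14))
    segs = analyze_track(_ut(t, s), breakpoints=[(0, 15), (15, 30)], seed=1)
    assert [g.label for g in segs] == ["stationary", "processive"]
    assert segs[1].v == pytest.approx(9.0)
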