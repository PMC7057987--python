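"""Streaming entry marking, correction, warning, and deviation arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dsdmonitor as dm
from dsdmonitor.monitor import (
    DeviationBin,
    Direction,
    check_warning,
    correct_mark,
    deviation,
    deviation_summary,
    mark_entry,
    monitor_stream,
    score_stream,
)

CFG = dm.MonitorConfig(cutoff=0.42)


class MeanIntensityScorer:
    """Stateless stand-in classifier: score = mean normalized intensity."""

    def predict_score(self, frames):
        frames = np.asarray(frames, dtype=float)
        return frames.reshape(len(frames), -1).mean(axis=1) / 255.0


class TestScoreStream:
    def test_order_preserved_one_score_per_frame(self):
        frames = np.stack([np.full((8, 8), v, np.uint8) for v in (10, 200, 60)])
        s = score_stream(MeanIntensityScorer(), frames)
        assert s.shape == (3,)
        assert s[1] > s[2] > s[0]

    def test_identical_frames_identical_scores(self):
        frames = np.zeros((4, 8, 8), np.uint8) + 77
        s = score_stream(MeanIntensityScorer(), frames)
        assert len(set(s.tolist())) == 1

    def test_chunked_equals_single_pass(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 256, (10, 8, 8)).astype(np.uint8)
        one = score_stream(MeanIntensityScorer(), frames, batch_size=256)
        chunked = score_stream(MeanIntensityScorer(), frames, batch_size=3)
        assert np.array_equal(one, chunked)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_stream(MeanIntensityScorer(), np.empty((0, 8, 8)))


class TestMarkEntry:
    def test_first_crossing_with_single_frame_confirmation(self):
        mark = mark_entry([0.1, 0.1, 0.9, 0.9, 0.9], CFG)
        assert mark.index == 2
        assert mark.time_s == pytest.approx(1.0)  # 2 * 500 ms

    def test_run_of_three_starts_at_same_index(self):
        cfg = dm.MonitorConfig(cutoff=0.42, m_confirm=3)
        assert mark_entry([0.1, 0.1, 0.9, 0.9, 0.9], cfg).index == 2

    def test_no_qualifying_run_returns_no_mark(self):
        cfg = dm.MonitorConfig(cutoff=0.42, m_confirm=2)
        assert mark_entry([0.9, 0.1, 0.1], cfg).index is None

    def test_marked_time_is_index_times_interval(self):
        cfg = dm.MonitorConfig(cutoff=0.5, interval_ms=250.0)
        mark = mark_entry([0.0, 0.0, 0.0, 1.0], cfg)
        assert mark.index == 3
        assert mark.time_s == pytest.approx(3 * 0.25)

    @settings(max_examples=50, deadline=None)
    @given(
        scores=st.lists(st.floats(0, 1), min_size=1, max_size=40),
        m=st.integers(1, 5),
    )
    def test_increasing_confirmation_never_marks_earlier(self, scores, m):
        a = mark_entry(scores, dm.MonitorConfig(cutoff=0.42, m_confirm=m)).index
        b = mark_entry(scores, dm.MonitorConfig(cutoff=0.42, m_confirm=m + 1)).index
        a = np.inf if a is None else a
        b = np.inf if b is None else b
        assert b >= a


class TestCorrectMark:
    def test_stomach_run_revokes_and_remarks(self):
        cfg = dm.MonitorConfig(cutoff=0.42, m_confirm=1, k_correct=3)
        scores = [0.1, 0.1, 0.9] + [0.1] * 3 + [0.9, 0.9, 0.9]
        mark = correct_mark(mark_entry(scores, cfg), scores, cfg)
        assert mark.index == 6
        assert len(mark.history) == 1
        assert mark.history[0][0] == 2 and mark.history[0][1] == 6

    def test_stable_when_dsd_persists(self):
        cfg = dm.MonitorConfig(cutoff=0.42, k_correct=3)
        scores = [0.1, 0.1, 0.9, 0.95, 0.99, 0.9]
        mark = correct_mark(mark_entry(scores, cfg), scores, cfg)
        assert mark.index == 2
        assert mark.history == []

    def test_short_interference_burst_is_corrected_to_truth(self):
        """A DSD-looking burst before true entry must not keep the mark."""
        entry = 30
        scores = np.zeros(60)
        scores[entry:] = 1.0
        scores[10:13] = 1.0  # misleading burst, stomach resumes after
        cfg = dm.MonitorConfig(cutoff=0.5, m_confirm=1, k_correct=3)
        mark = monitor_stream(scores, cfg)
        assert mark.index == entry
        assert len(mark.history) == 1

    def test_revocation_without_later_entry_leaves_no_mark(self):
        cfg = dm.MonitorConfig(cutoff=0.5, k_correct=2)
        scores = [0.9, 0.1, 0.1, 0.1]
        mark = monitor_stream(scores, cfg)
        assert mark.index is None
        assert mark.history[0][0] == 0 and mark.history[0][1] is None


class TestWarning:
    def test_two_hours_of_stomach_raises_at_limit_frame(self):
        scores = np.zeros(14_400)
        status = check_warning(scores, dm.MonitorConfig(cutoff=0.42))
        assert status.raised
        assert status.frame_index == 14_400
        assert status.time_s == pytest.approx(7200.0)

    def test_marked_entry_suppresses_warning(self):
        scores = np.zeros(14_400)
        scores[7200:] = 1.0  # entry at the 1-hour point
        status = check_warning(scores, dm.MonitorConfig(cutoff=0.42))
        assert not status.raised

    def test_zero_limit_raises_immediately_when_unmarked(self):
        status = check_warning([0.0], dm.MonitorConfig(cutoff=0.42, warning_limit_s=0.0))
        assert status.raised and status.frame_index == 0

    def test_no_warning_before_limit(self):
        status = check_warning(np.zeros(100), dm.MonitorConfig(cutoff=0.42))
        assert not status.raised


class TestDeviation:
    def test_published_worked_example(self):
        """Marks 1521 vs 1466 at 500 ms: 54 frames between, 27 s delayed."""
        r = deviation(1521, 1466, 500.0)
        assert r.frames == 54
        assert r.direction is Direction.DELAYED
        assert r.time_s == pytest.approx(27.0)
        assert r.bin is DeviationBin.LT_1MIN
        assert not r.failure

    def test_identical_marks_are_exact(self):
        r = deviation(100, 100, 500.0)
        assert r.frames == 0 and r.direction is Direction.EXACT and r.time_s == 0.0

    def test_large_advance_is_a_failure(self):
        r = deviation(100, 1200, 500.0)
        assert r.frames == 1099
        assert r.direction is Direction.AHEAD
        assert r.time_s == pytest.approx(549.5)
        assert r.failure  # > 480 s

    @pytest.mark.parametrize(
        "seconds,expected",
        [(0.0, DeviationBin.LT_1MIN), (59.5, DeviationBin.LT_1MIN),
         (60.0, DeviationBin.BETWEEN_1_3MIN), (179.5, DeviationBin.BETWEEN_1_3MIN),
         (180.0, DeviationBin.GE_3MIN), (481.0, DeviationBin.GE_3MIN)],
    )
    def test_bin_edges_half_open(self, seconds, expected):
        frames = int(seconds * 2)  # at 500 ms/frame
        r = deviation(frames + 1, 0, 500.0)
        assert r.time_s == pytest.approx(seconds)
        assert r.bin is expected

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            deviation(-1, 5)

    @settings(max_examples=60, deadline=None)
    @given(a=st.integers(0, 5000), b=st.integers(0, 5000))
    def test_swapping_marks_flips_direction_only(self, a, b):
        r1, r2 = deviation(a, b), deviation(b, a)
        assert r1.frames == r2.frames
        assert r1.time_s == r2.time_s
        assert r1.bin is r2.bin and r1.failure == r2.failure
        if a != b:
            assert {r1.direction, r2.direction} == {Direction.AHEAD, Direction.DELAYED}


class TestDeviationSummary:
    def test_five_failures_of_115_within_rate(self):
        """110 of 115 monitored cases within +/-8 min -> 95.7 %."""
        ok = [deviation(i + 10, 10) for i in range(110)]  # small deviations
        bad = [deviation(3000, 10) for _ in range(5)]  # far beyond 8 min
        summary = deviation_summary(ok + bad)
        assert summary["failures"] == 5
        assert summary["within_8min_percent"] == 95.7

    def test_all_exact_marks_fall_in_first_bin(self):
        summary = deviation_summary([deviation(5, 5) for _ in range(10)])
        assert summary["percent"]["<1min"] == 100.0
        assert summary["failures"] == 0

    def test_counts_match_per_report_loop(self):
        rng = np.random.default_rng(0)
        reports = [deviation(int(a), int(b)) for a, b in rng.integers(0, 4000, (50, 2))]
        summary = deviation_summary(reports)
        by_bin = {b.value: 0 for b in DeviationBin}
        failures = 0
        for r in reports:
            by_bin[r.bin.value] += 1
            failures += r.failure
        assert summary["counts"] == by_bin
        assert summary["failures"] == failures

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            deviation_summary([])


class TestEndToEndRecovery:
    def test_oracle_classifier_recovers_entry_exactly(self):
        """score = label implies the mark lands on the true entry frame."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            spec = dm.StreamSpec(
                total_frames=120,
                entry_index=int(rng.integers(20, 100)),
                shape=(32, 32),
                seed=seed,
                events=(
                    dm.InterferenceEvent(dm.InterferenceKind.FOAM, int(rng.integers(0, 80)), 5),
                ),
                stagnation=((int(rng.integers(0, 90)), 8),),
            )
            stream = dm.generate_stream(spec)
            scores = stream.labels.astype(float)
            cfg = dm.MonitorConfig(cutoff=0.5, m_confirm=1, k_correct=3)
            assert monitor_stream(scores, cfg).index == spec.entry_index

    def test_noise_tolerant_recovery_with_confirmation_runs(self):
        """5 % score flips, M = K = 3: mark stays within 3 frames of truth."""
        rng = np.random.default_rng(1234)
        hits = 0
        n_streams = 60
        for _ in range(n_streams):
            entry = int(rng.integers(100, 300))
            labels = (np.arange(400) >= entry).astype(float)
            flip = rng.random(400) < 0.05
            scores = np.where(flip, 1.0 - labels, labels)
            cfg = dm.MonitorConfig(cutoff=0.5, m_confirm=3, k_correct=3)
            mark = monitor_stream(scores, cfg)
            if mark.index is not None and abs(mark.index - entry) <= 3:
                hits += 1
        assert hits / n_streams >= 0.9
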