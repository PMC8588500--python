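import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgflow as ef
from emgflow.preprocessing import DegenerateInputError


def _rec(signal, fs=100.0, labels=None):
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] == 1:
        signal = signal.T
    if labels is None:
        labels = np.zeros(signal.shape[0], dtype=int)
    return ef.MultichannelRecording(signal=signal, fs=fs, labels=labels)


class TestZscore:
    def test_standardizes_each_channel(self):
        rec = _rec(np.column_stack([np.arange(1, 4.0), [10.0, 20, 60]]))
        out = ef.zscore(rec)
        np.testing.assert_allclose(out.signal.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(out.signal.std(axis=0), 1, atol=1e-9)

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((200, 2)))
        once = ef.zscore(rec)
        twice = ef.zscore(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-12)

    def test_constant_channel_rejected_by_name(self):
        rec = _rec(np.column_stack([np.arange(5.0), np.full(5, 3.0)]))
        with pytest.raises(DegenerateInputError, match="1"):
            ef.zscore(rec)


class TestTeagerEnergy:
    def test_constant_signal_gives_zero(self):
        np.testing.assert_allclose(ef.teager_energy(np.full(20, 7.0)), 0.0)

    def test_unit_ramp_gives_one(self):
        np.testing.assert_allclose(ef.teager_energy(np.arange(20.0)), 1.0)

    def test_sinusoid_closed_form(self):
        # psi[A cos(wn + phi)] = A^2 sin^2(w) at interior samples
        A, w, phi = 2.0, 0.3, 0.71
        n = np.arange(200)
        psi = ef.teager_energy(A * np.cos(w * n + phi))
        np.testing.assert_allclose(psi[1:-1], A ** 2 * np.sin(w) ** 2, atol=1e-9)

    def test_boundaries_replicate_and_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(50)
        psi = ef.teager_energy(x)
        assert psi.shape == x.shape
        assert psi[0] == psi[1] and psi[-1] == psi[-2]

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            ef.teager_energy([1.0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-10, max_value=10, allow_nan=False),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_scale_quadratic(self, a, seed):
        x = np.random.default_rng(seed).standard_normal(30)
        np.testing.assert_allclose(ef.teager_energy(a * x), a ** 2 * ef.teager_energy(x),
                                   atol=1e-8 * max(1.0, a ** 2))


class TestSmoothedChannelEnergy:
    def test_single_channel_n1_equals_teager(self):
        x = np.random.default_rng(2).standard_normal(40)
        rec = _rec(x)
        np.testing.assert_allclose(ef.smoothed_channel_energy(rec, 1),
                                   ef.teager_energy(x))

    def test_two_channels_average(self):
        # channel energies e and 3e -> average 2e
        x = np.random.default_rng(3).standard_normal(40)
        rec = _rec(np.column_stack([x, np.sqrt(3.0) * x]))
        np.testing.assert_allclose(ef.smoothed_channel_energy(rec, 1),
                                   2.0 * ef.teager_energy(x), atol=1e-12)

    def test_constant_energy_invariant_to_n(self):
        rec = _rec(np.arange(50.0))  # ramp: Teager energy 1 everywhere
        for n in (1, 5, 20):
            np.testing.assert_allclose(ef.smoothed_channel_energy(rec, n), 1.0)

    def test_oversized_window_rejected(self):
        with pytest.raises(DegenerateInputError):
            ef.smoothed_channel_energy(_rec(np.arange(10.0)), 11)


class TestDetectActive:
    def test_all_zero_energy_gives_no_intervals(self):
        acts = ef.detect_active(np.zeros(100), threshold=0.5, min_dur=3)
        assert acts.intervals == []

    def test_single_block_detected_exactly(self):
        energy = np.zeros(300)
        energy[100:200] = 1.0
        acts = ef.detect_active(energy, threshold=0.5, min_dur=3)
        assert acts.intervals == [(100, 200)]

    def test_blip_shorter_than_min_dur_ignored(self):
        energy = np.zeros(100)
        energy[50:52] = 1.0
        acts = ef.detect_active(energy, threshold=0.5, min_dur=3)
        assert acts.intervals == []

    def test_short_subthreshold_gap_bridged(self):
        # a 2-sample dip does not close an interval when min_dur=3
        energy = np.ones(60)
        energy[:10] = 0.0
        energy[30:32] = 0.0
        energy[50:] = 0.0
        acts = ef.detect_active(energy, threshold=0.5, min_dur=3)
        assert acts.intervals == [(10, 50)]

    def test_invariant_to_energy_values_between_crossings(self):
        rng = np.random.default_rng(4)
        base = np.zeros(200)
        base[60:140] = 1.0
        wobble = base.copy()
        wobble[60:140] = 1.0 + rng.random(80) * 5  # any supra-threshold values
        thr = 0.5
        a1 = ef.detect_active(base, thr, 4).intervals
        a2 = ef.detect_active(wobble, thr, 4).intervals
        assert a1 == a2


class TestRelabel:
    def test_fixed_point_when_intervals_match_label_runs(self):
        labels = np.zeros(100, dtype=int)
        labels[20:50] = 3
        rec = _rec(np.random.default_rng(5).standard_normal((100, 2)), labels=labels)
        out = ef.relabel(rec, ef.ActivityIntervals(intervals=[(20, 50)]))
        np.testing.assert_array_equal(out.labels, labels)

    def test_empty_intervals_give_all_rest(self):
        labels = np.zeros(50, dtype=int)
        labels[10:30] = 2
        rec = _rec(np.random.default_rng(6).standard_normal((50, 1)), labels=labels)
        out = ef.relabel(rec, ef.ActivityIntervals(intervals=[]))
        assert not out.labels.any()

    def test_majority_label_wins_inside_interval(self):
        labels = np.zeros(100, dtype=int)
        labels[10:16] = 1
        labels[16:40] = 2
        rec = _rec(np.zeros((100, 1)), labels=labels)
        out = ef.relabel(rec, ef.ActivityIntervals(intervals=[(8, 42)]))
        assert set(out.labels[8:42]) == {2}

    def test_unlabeled_interval_borrows_nearest_with_warning(self):
        labels = np.zeros(100, dtype=int)
        labels[10:20] = 4
        rec = _rec(np.zeros((100, 1)), labels=labels)
        with pytest.warns(UserWarning, match="borrowing"):
            out = ef.relabel(rec, ef.ActivityIntervals(intervals=[(60, 70)]))
        assert set(out.labels[60:70]) == {4}

    def test_out_of_bounds_interval_rejected(self):
        rec = _rec(np.zeros((50, 1)))
        with pytest.raises(ValueError):
            ef.relabel(rec, ef.ActivityIntervals(intervals=[(40, 60)]))


class TestSegment:
    def test_window_count_is_floor_of_run_length(self):
        labels = np.zeros(150, dtype=int)
        labels[0:100] = 1
        rec = _rec(np.random.default_rng(7).standard_normal((150, 2)), labels=labels)
        wins = ef.segment(rec, 400)  # 40 samples at 100 Hz
        assert len(wins) == 2

    def test_run_shorter_than_window_yields_nothing(self):
        labels = np.zeros(100, dtype=int)
        labels[10:30] = 1
        rec = _rec(np.zeros((100, 1)), labels=labels)
        assert ef.segment(rec, 400) == []

    def test_alternating_runs_one_window_each_label_pure(self):
        labels = np.tile(np.repeat([1, 2], 40), 3)
        rec = _rec(np.random.default_rng(8).standard_normal((240, 1)), labels=labels)
        wins = ef.segment(rec, 400)
        assert len(wins) == 6
        assert [w.label for w in wins] == [1, 2, 1, 2, 1, 2]

    def test_no_window_straddles_two_labels(self, small_recording, small_plan):
        rec = small_recording
        wins = ef.segment(rec, 400)
        for w in wins:
            run = rec.labels[w.start_sample:w.start_sample + w.data.shape[0]]
            assert set(run) == {w.label}

    def test_total_emitted_samples_bounded_by_labeled_samples(self, small_recording):
        wins = ef.segment(small_recording, 400)
        emitted = sum(w.data.shape[0] for w in wins)
        assert emitted <= np.count_nonzero(small_recording.labels)


class TestRelabelRecovery:
    def test_relabeled_onsets_beat_jittered_labels(self):
        """With 200 ms label jitter the detector must land closer to the true
        onsets than the emitted labels do, in mean absolute error."""
        plan = ef.benchmark_plan(n_repetitions=5, seed=11, label_jitter_ms=200.0)
        rec = ef.zscore(ef.simulate_recording(plan))
        relabeler = ef.TeagerRelabeler()
        relabeler.transform(rec)
        true_on = np.array([s for s, _, _ in ef.true_intervals(plan)])
        det_on = np.array([s for s, _ in relabeler.intervals_.intervals])
        lab = rec.labels
        jit_on = np.flatnonzero(np.diff((lab > 0).astype(int)) == 1) + 1
        mae_det = np.mean([np.abs(det_on - o).min() for o in true_on])
        mae_jit = np.mean([np.abs(jit_on - o).min() for o in true_on])
        assert mae_det < mae_jit
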