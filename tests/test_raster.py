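"""Vmed, binarization, window construction and on-state densities."""

import numpy as np
import pytest

from dualgamma.hfa import BipolarSite, HfaSeries
from dualgamma.io_formats import VerbalEvent
from dualgamma.raster import (AnalysisWindow, BinarySeries, WindowKind,
                              binarize_series, build_raster, compute_vmed,
                              define_t1_best_windows, define_t2_free_windows,
                              define_t2_windows, select_fastest_correct,
                              window_on_density)
from tests.conftest import make_trials


def _series(values):
    return HfaSeries(site=BipolarSite("A1-A2", "A", "A1", "A2"),
                     values=np.asarray(values, float))


class TestFastestCorrect:
    def test_floor_of_half(self):
        trials = make_trials([0.5 + 0.001 * i for i in range(100)])
        assert len(select_fastest_correct(trials)) == 50

    def test_smallest_rts_selected(self):
        trials = make_trials([0.5, 0.6, 0.7, 0.8])
        chosen = select_fastest_correct(trials)
        assert sorted(t.response_time for t in chosen) == [0.5, 0.6]

    def test_ties_broken_by_trial_index(self):
        trials = make_trials([0.5] * 4)
        chosen = select_fastest_correct(trials)
        assert sorted(t.trial_index for t in chosen) == [0, 1]

    def test_no_correct_trials_is_error(self):
        trials = make_trials([None, None])
        with pytest.raises(ValueError):
            select_fastest_correct(trials)


class TestVmed:
    def test_pooled_median_small(self):
        # one trial: baseline = the 12 samples right before the onset sample
        values = np.full(256, 100.0)
        values[116:128] = np.arange(1, 13)  # onset at sample 128 (t = 2 s)
        trials = make_trials([0.5], start=2.0)
        rec = compute_vmed(_series(values), trials)
        assert rec.vmed == 6.5
        assert rec.n_baseline_samples == 12

    def test_constant_series(self):
        trials = make_trials([0.5] * 4, start=2.0, gap=3.0)
        rec = compute_vmed(_series(np.full(64 * 40, 100.0)), trials)
        assert rec.vmed == 100.0

    def test_matches_sort_based_oracle(self, rng):
        """Pooled median across 50 trials equals the brute-force sorted
        mid-value of the same pool."""
        trials = make_trials([0.5] * 50, start=2.0, gap=3.0)
        values = rng.uniform(0, 200, 64 * 200)
        series = _series(values)
        rec = compute_vmed(series, trials)
        pool = np.concatenate([
            values[round(t.target_onset * 64) - 12: round(t.target_onset * 64)]
            for t in trials])
        s = np.sort(pool)
        oracle = 0.5 * (s[s.size // 2 - 1] + s[s.size // 2])  # even-sized pool
        assert rec.vmed == pytest.approx(oracle, abs=0)
        assert rec.vmed == pytest.approx(100.0, rel=0.1)

    def test_baseline_outside_session_is_error(self):
        trials = make_trials([0.5], start=0.05)
        with pytest.raises(ValueError):
            compute_vmed(_series(np.ones(6400)), trials)


class TestBinarize:
    def test_strictly_greater(self):
        binary = binarize_series(_series([1, 2, 3, 4]), 2.5)
        assert binary.values.tolist() == [0, 0, 1, 1]

    def test_equality_is_off(self):
        binary = binarize_series(_series([5.0, 5.0, 5.0]), 5.0)
        assert binary.values.sum() == 0

    def test_median_split_property(self, rng):
        """On-fraction over the Vmed-defining pool is [0.5 - 1/n, 0.5] for
        continuous data (the defining property of the median split)."""
        trials = make_trials([0.5] * 50, start=2.0, gap=3.0)
        series = _series(rng.normal(100, 20, 64 * 200))
        rec = compute_vmed(series, trials)
        binary = binarize_series(series, rec)
        pool = np.concatenate([
            binary.values[round(t.target_onset * 64) - 12: round(t.target_onset * 64)]
            for t in trials])
        frac = pool.mean()
        assert 0.5 - 1.0 / pool.size <= frac <= 0.5
        assert 0.49 <= frac <= 0.51

    def test_binarization_is_monotone(self):
        """Raising any sample's HFA never turns an on sample off."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, derandomize=True)
        @given(st.lists(st.floats(0, 200, allow_nan=False), min_size=4, max_size=64),
               st.floats(0, 200), st.integers(0, 63), st.floats(0, 50))
        def check(values, vmed, idx, bump):
            if idx >= len(values):
                idx = idx % len(values)
            before = binarize_series(_series(values), vmed).values
            raised = list(values)
            raised[idx] += bump
            after = binarize_series(_series(raised), vmed).values
            assert np.all(after >= before)

        check()

    def test_density_invariant_under_rescaling(self, rng):
        trials = make_trials([0.5] * 20, start=2.0, gap=3.0)
        series = _series(rng.normal(100, 20, 64 * 100))
        scaled = _series(3.0 * series.values)
        b1 = binarize_series(series, compute_vmed(series, trials))
        b2 = binarize_series(scaled, compute_vmed(scaled, trials))
        assert np.array_equal(b1.values, b2.values)


class TestRasterBuild:
    def test_row_ordering(self, rng):
        trials = make_trials([0.9, 0.5, 0.7], correct=[True, True, False],
                             start=5.0, gap=6.0)
        binary = BinarySeries("A1-A2", "DT",
                              (rng.random(64 * 40) < 0.5).astype(np.uint8), 64.0)
        ras = build_raster(binary, trials)
        # incorrect block first (RT 0.7), then correct sorted by RT
        assert [t.trial_index for t in ras.trials] == [2, 1, 0]

    def test_all_on_series(self):
        trials = make_trials([0.5] * 3, start=5.0, gap=6.0)
        binary = BinarySeries("A1-A2", "DT", np.ones(64 * 40, np.uint8), 64.0)
        ras = build_raster(binary, trials)
        assert ras.values.shape == (3, 256)
        assert ras.values.all()


class TestWindows:
    def test_one_t2_window_per_response(self):
        verbals = [VerbalEvent(10.0 + 8.0 * k) for k in range(16)]
        windows = define_t2_windows(verbals)
        assert len(windows) == 16
        assert (windows[0].start, windows[0].end) == (8.0, 10.0)

    def test_early_response_dropped(self):
        assert define_t2_windows([VerbalEvent(1.0)]) == []

    def test_t2_free_tiling_oracle(self):
        """Responses at 10 s and 30 s in a 40 s session: margins leave
        [0, 8), [12, 28), [32, 40) -> 4 + 8 + 4 = 16 windows."""
        verbals = [VerbalEvent(10.0), VerbalEvent(30.0)]
        windows = define_t2_free_windows(verbals, 40.0)
        assert len(windows) == 16
        expected_starts = ([0, 2, 4, 6] + [12, 14, 16, 18, 20, 22, 24, 26]
                           + [32, 34, 36, 38])
        assert [w.start for w in windows] == pytest.approx(expected_starts)

    def test_dense_responses_leave_nothing(self):
        verbals = [VerbalEvent(3.0 * (k + 1)) for k in range(10)]
        assert define_t2_free_windows(verbals, 33.0) == []

    def test_no_responses_tiles_whole_session(self):
        assert len(define_t2_free_windows([], 10.0)) == 5

    def test_windows_respect_margins(self, rng):
        """Property: no T2-free window ever comes within the margin of a
        response, and windows of one kind never overlap."""
        for _ in range(100):
            onsets = np.sort(rng.uniform(5, 295, rng.integers(1, 15)))
            verbals = [VerbalEvent(float(o)) for o in onsets]
            free = define_t2_free_windows(verbals, 300.0)
            for w in free:
                assert all(o <= w.start - 2.0 + 1e-9 or o >= w.end + 2.0 - 1e-9
                           for o in onsets)
            for a, b in zip(free[:-1], free[1:]):
                assert b.start >= a.end - 1e-9

    def test_t1_best_windows(self):
        trials = make_trials([0.5, 0.9, 0.7], start=10.0, gap=10.0)
        windows = define_t1_best_windows(trials, 2)
        assert [w.anchor.trial_index for w in windows] == [0, 2]
        assert windows[0].start == pytest.approx(10.0 - 0.8)
        assert windows[0].end == pytest.approx(10.0 + 1.2)


class TestDensity:
    def _binary(self, values):
        return BinarySeries("A1-A2", "DT", np.asarray(values, np.uint8), 64.0)

    def test_all_on(self):
        w = AnalysisWindow(WindowKind.T2, 0.0, 2.0)
        d = window_on_density(self._binary(np.ones(128)), [w])[0]
        assert d.density == 1.0 and d.n_samples == 128

    def test_alternating(self):
        w = AnalysisWindow(WindowKind.T2, 0.0, 2.0)
        d = window_on_density(self._binary(np.arange(128) % 2), [w])[0]
        assert d.density == 0.5

    def test_count_oracle(self):
        values = np.zeros(128)
        values[:32] = 1
        w = AnalysisWindow(WindowKind.T2, 0.0, 2.0)
        assert window_on_density(self._binary(values), [w])[0].density == 0.25

    def test_window_outside_session_is_error(self):
        w = AnalysisWindow(WindowKind.T2, 10.0, 12.0)
        with pytest.raises(ValueError, match="10"):
            window_on_density(self._binary(np.ones(128)), [w])
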