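"""Rank-sum machinery and the five site-level detectors."""

import itertools

import numpy as np
import pytest
import scipy.stats

from dualgamma.io_formats import TrialEvent
from dualgamma.neurostats import (automatization_test, binary_ranksum,
                                  binary_ranksum_counts, compare_st_dt,
                                  detect_t1_response, detect_t2_density,
                                  interference_test)
from dualgamma.raster import AnalysisWindow, BinaryRaster, BinarySeries, WindowKind
from tests.conftest import make_trials


def enumeration_ranksum_p(a, b, alternative="two-sided"):
    """Brute-force permutation oracle: midrank rank-sum of group a over all
    assignments of the pooled values."""
    pool = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pool)
    n_a = len(a)
    idx_all = range(len(pool))
    w_obs = ranks[:n_a].sum()
    e_w = n_a * (len(pool) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(idx_all, n_a):
        w = ranks[list(combo)].sum()
        if alternative == "two-sided":
            count += abs(w - e_w) >= abs(w_obs - e_w) - 1e-12
        elif alternative == "greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
        total += 1
    return count / total


class TestBinaryRanksum:
    def test_identical_multisets_give_p_one(self):
        a = [1, 1, 0, 0, 1]
        assert binary_ranksum(a, a) == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration_oracle(self, alternative):
        """For n <= 20 the implementation is exact: verify against the
        brute-force permutation oracle on a sweep of configurations."""
        configs = [(8, 10, 2, 10), (5, 6, 1, 6), (3, 4, 4, 8), (0, 5, 5, 5),
                   (2, 7, 6, 9), (6, 6, 3, 6), (1, 3, 2, 3), (4, 9, 9, 11)]
        for a_ones, a_n, b_ones, b_n in configs:
            a = [1] * a_ones + [0] * (a_n - a_ones)
            b = [1] * b_ones + [0] * (b_n - b_ones)
            expected = enumeration_ranksum_p(a, b, alternative)
            assert binary_ranksum(a, b, alternative) == pytest.approx(expected, abs=1e-12), \
                (a_ones, a_n, b_ones, b_n, alternative)

    def test_maximal_separation(self):
        p = binary_ranksum([1] * 50, [0] * 50)
        assert p < 1e-10

    def test_asymptotic_agrees_with_scipy(self, rng):
        """Dual route: the counts-based normal approximation must match
        scipy's tie-corrected Mann-Whitney on the expanded samples."""
        for _ in range(20):
            a_n, b_n = rng.integers(15, 60, 2)
            a = (rng.random(a_n) < rng.uniform(0.2, 0.8)).astype(int)
            b = (rng.random(b_n) < rng.uniform(0.2, 0.8)).astype(int)
            if len(set(np.concatenate([a, b]))) < 2:
                continue
            ours = binary_ranksum_counts(a.sum(), a_n, b.sum(), b_n, "two-sided")
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="asymptotic").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            binary_ranksum([], [0, 1])


def _raster_from_probs(probs, n_trials, rng, window=(-1.0, 3.0)):
    """Binary raster with per-column on-probabilities (chronological rows)."""
    values = (rng.random((n_trials, probs.size)) < probs).astype(np.uint8)
    trials = make_trials([0.5 + 0.001 * i for i in range(n_trials)],
                         start=5.0, gap=5.0)
    return BinaryRaster("A1-A2", values, trials, window, 64.0, "DT")


class TestT1Detection:
    def test_injected_span_recovered(self, rng):
        """On-probability 0.9 inside [200, 700) ms vs 0.5 elsewhere: most
        of the injected span is flagged, little outside."""
        probs = np.full(256, 0.5)
        span = slice(64 + 13, 64 + 45)  # [200, 700) ms after onset
        probs[span] = 0.9
        res = detect_t1_response(_raster_from_probs(probs, 50, rng),
                                 restrict_fastest_correct=False)
        in_span = res.mask[span]
        out_span = np.concatenate([res.mask[:span.start], res.mask[span.stop:]])
        assert in_span.mean() >= 0.8
        assert out_span.mean() <= 0.05
        assert any(s0 <= span.start < s1 for s0, s1 in res.segments)

    def test_null_raster_mostly_clean(self, rng):
        flagged = sum(
            detect_t1_response(_raster_from_probs(np.full(256, 0.5), 50,
                                                  np.random.default_rng(s)),
                               restrict_fastest_correct=False).n_significant > 0
            for s in range(20))
        assert flagged <= 2

    def test_constant_raster_flags_nothing(self, rng):
        res = detect_t1_response(_raster_from_probs(np.ones(256), 30, rng),
                                 restrict_fastest_correct=False)
        assert res.n_significant == 0
        assert np.all(res.p_values == 1.0)

    def test_too_few_trials_is_error(self, rng):
        with pytest.raises(ValueError):
            detect_t1_response(_raster_from_probs(np.full(256, 0.5), 5, rng),
                               restrict_fastest_correct=False)


def _windows(starts, kind=WindowKind.T2_FREE, length=2.0):
    return [AnalysisWindow(kind, s, s + length) for s in starts]


class TestT2Density:
    def test_pct_plus_count_oracle(self):
        """Two 128-sample windows holding 96 and 64 on-samples pool to
        160/256 = 62.5%."""
        values = np.zeros(64 * 60, np.uint8)
        w1, w2 = AnalysisWindow(WindowKind.T2, 10.0, 12.0), AnalysisWindow(WindowKind.T2, 20.0, 22.0)
        values[640:640 + 96] = 1
        values[1280:1280 + 64] = 1
        binary = BinarySeries("A1-A2", "DT", values, 64.0)
        free = _windows([30 + 2 * i for i in range(10)])
        res = detect_t2_density(binary, [w1, w2], free, n_surrogates=100, seed=0)
        assert res.pct_plus == pytest.approx(62.5)

    def test_extreme_density_minimal_p(self, rng):
        """All-on T2-windows against fair-coin elsewhere: p = 1/10001,
        significant for any Bonferroni denominator up to 500."""
        values = (rng.random(64 * 300) < 0.5).astype(np.uint8)
        t2 = _windows([10.0, 50.0], WindowKind.T2)
        for w in t2:
            values[int(w.start * 64):int(w.end * 64)] = 1
        binary = BinarySeries("A1-A2", "DT", values, 64.0)
        free = _windows([100 + 2 * i for i in range(60)])
        res = detect_t2_density(binary, t2, free, n_surrogates=10_000,
                                n_sites=500, seed=1)
        assert res.p == pytest.approx(1 / 10_001)
        assert res.significant  # 1/10001 < 0.05/500

    def test_granularity_guard(self, rng):
        binary = BinarySeries("A1-A2", "DT",
                              (rng.random(64 * 100) < 0.5).astype(np.uint8), 64.0)
        t2 = _windows([10.0], WindowKind.T2)
        free = _windows([20 + 2 * i for i in range(20)])
        with pytest.raises(ValueError, match="n_surrogates"):
            detect_t2_density(binary, t2, free, n_surrogates=100, n_sites=50, seed=0)


class TestInterference:
    def test_identical_densities(self):
        d = [0.5, 0.6, 0.4, 0.5, 0.7, 0.5]
        v = interference_test(d, d, n_sites=10)
        assert v.p == 1.0 and not v.significant

    def test_uniform_positive_shift(self, rng):
        t1 = rng.uniform(0.2, 0.5, 30)
        v = interference_test(t1 + 0.3, t1, n_sites=100)
        assert v.p < 0.05 / 100
        assert v.significant

    def test_underpowered_below_five_pairs(self):
        v = interference_test([0.9] * 4, [0.1] * 4, n_sites=1)
        assert v.underpowered and not v.significant


class TestCompareStDt:
    def test_identical_rasters_flag_nothing(self, rng):
        ras = _raster_from_probs(np.full(256, 0.5), 40, rng)
        res = compare_st_dt(ras, ras)
        assert res.n_significant == 0

    def test_condition_difference_recovered(self, rng):
        probs_st = np.full(256, 0.5)
        span = slice(64 + 13, 64 + 45)
        probs_st[span] = 0.9
        st = _raster_from_probs(probs_st, 60, rng)
        dt = _raster_from_probs(np.full(256, 0.5), 60, np.random.default_rng(5))
        res = compare_st_dt(st, dt)
        assert res.mask[span].mean() >= 0.8
        mask_out = np.concatenate([res.mask[:span.start], res.mask[span.stop:]])
        assert mask_out.mean() <= 0.05


class TestAutomatization:
    def test_group_size_is_twenty_percent(self, rng):
        ras = _raster_from_probs(np.full(256, 0.5), 250, rng)
        res = automatization_test(ras)
        assert res.p > 0.0  # 50-trial groups, valid test
        # 20% of 250 trials = 50 per group: check via the error path boundary
        with pytest.raises(ValueError):
            automatization_test(_raster_from_probs(np.full(256, 0.5), 4, rng,),
                                fraction=0.2)

    def test_ramp_detected(self, rng):
        n = 100
        trials = make_trials([0.5] * n, start=5.0, gap=5.0)
        probs = np.linspace(0.3, 0.7, n)
        values = (rng.random((n, 256)) < 0.5).astype(np.uint8)
        cols = slice(64 + 58, 64 + 77)  # the [900, 1200) ms window
        values[:, cols] = (rng.random((n, 19)) < probs[:, None]).astype(np.uint8)
        ras = BinaryRaster("A1-A2", values, trials, (-1.0, 3.0), 64.0, "ST")
        res = automatization_test(ras)
        assert res.significant
        assert res.group_means[0] < res.group_means[1]
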