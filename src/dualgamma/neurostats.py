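"""Site-level statistics on binarized HFA.

Five detectors, all operating on on/off series or rasters:

* task-evoked responses: per-sample rank-sum of each epoch column against
  the pooled pre-stimulus baseline, FDR-corrected across samples;
* secondary-task density: pooled on-percentage in T2-windows against a
  surrogate distribution from random T2-free window sets, Bonferroni over
  sites;
* interference: paired signed-rank of T2-window densities against densities
  around the fastest correct trials, Bonferroni over sites;
* single-task vs dual-task: per-sample rank-sum between matched numbers of
  fastest correct trials of the two sessions, FDR across samples;
* automatization: first vs last 20% of trials on per-trial densities in a
  late epoch window.

Rank-sum tests on binary data reduce to the hypergeometric distribution of
the number of "on" values in one group; they are computed exactly by
enumeration for n <= 20 and by the tie-corrected normal approximation
otherwise.  Empirical (surrogate) p-values use (k + 1)/(n + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .raster import (BASELINE_N_SAMPLES, BinaryRaster, BinarySeries,
                     DensitySample, select_fastest_correct)
from .timebase import n_samples, sample_index

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_MAX_N = 20
DEFAULT_N_SURROGATES = 10_000
AUTOMATIZATION_WINDOW = (0.9, 1.2)   # s relative to target onset
AUTOMATIZATION_FRACTION = 0.2


@dataclass
class SamplewiseTest:
    site_label: str
    p_values: np.ndarray        # per epoch sample
    mask: np.ndarray            # FDR-adjusted significance at q
    direction: np.ndarray       # +1 above reference, -1 below, 0 tie
    q: float
    segments: list[tuple[int, int]] = field(default_factory=list)  # [start, end) cols
    underpowered: bool = False

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


@dataclass
class SiteTestResult:
    site_label: str
    pct_plus: float             # pooled on-percentage in T2-windows
    pct_minus: np.ndarray       # surrogate distribution
    p: float
    alpha_corrected: float
    significant: bool
    n_windows: int


@dataclass
class InterferenceVerdict:
    site_label: str
    t2_densities: np.ndarray
    t1_densities: np.ndarray
    statistic: float
    p: float
    alpha_corrected: float
    significant: bool
    underpowered: bool = False


@dataclass
class TwoGroupResult:
    site_label: str
    statistic: float
    p: float
    alpha: float
    significant: bool
    group_means: tuple[float, float]


# ---------------------------------------------------------------------------
# Rank-sum on binary data
# ---------------------------------------------------------------------------

def _binary_u(a_ones, a_n, b_ones, b_n):
    """Mann-Whitney U of group a vs b for 0/1 data, with midrank ties."""
    a_zeros, b_zeros = a_n - a_ones, b_n - b_ones
    return a_ones * b_zeros + 0.5 * (a_ones * b_ones + a_zeros * b_zeros)


def binary_ranksum_counts(a_ones, a_n, b_ones, b_n, alternative="two-sided"):
    """Vectorized tie-corrected normal-approximation rank-sum p-value for
    binary samples summarized by counts.  Continuity-corrected."""
    a_ones = np.asarray(a_ones, float)
    a_n = np.asarray(a_n, float)
    b_ones = np.asarray(b_ones, float)
    b_n = np.asarray(b_n, float)
    n = a_n + b_n
    ones = a_ones + b_ones
    zeros = n - ones
    u = _binary_u(a_ones, a_n, b_ones, b_n)
    mu = a_n * b_n / 2.0
    tie_term = ((ones ** 3 - ones) + (zeros ** 3 - zeros)) / (n * (n - 1.0))
    var = a_n * b_n / 12.0 * ((n + 1.0) - tie_term)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        if alternative == "two-sided":
            z = (np.abs(u - mu) - 0.5) / sd
            p = 2.0 * scipy.stats.norm.sf(np.maximum(z, 0.0))
        elif alternative == "greater":
            p = scipy.stats.norm.sf((u - mu - 0.5) / sd)
        elif alternative == "less":
            p = scipy.stats.norm.sf((mu - u - 0.5) / sd)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = np.where(sd > 0, p, 1.0)
    return np.minimum(np.asarray(p, float), 1.0)


def _binary_ranksum_exact(a_ones: int, a_n: int, b_ones: int, b_n: int,
                          alternative: str) -> float:
    """Exact rank-sum p by enumeration of the hypergeometric configurations.

    For binary data the rank-sum statistic is a strictly increasing function
    of the number of ones in group a, so tail probabilities of the
    hypergeometric law of that count give the exact permutation p-value.
    """
    n, ones = a_n + b_n, a_ones + b_ones
    rv = scipy.stats.hypergeom(n, ones, a_n)
    if alternative == "greater":
        return float(rv.sf(a_ones - 1))
    if alternative == "less":
        return float(rv.cdf(a_ones))
    mean = a_n * ones / n
    ks = np.arange(max(0, ones - b_n), min(a_n, ones) + 1)
    p = rv.pmf(ks)[np.abs(ks - mean) >= abs(a_ones - mean) - 1e-12].sum()
    return float(min(p, 1.0))


def binary_ranksum(a, b, alternative: str = "two-sided") -> float:
    """Rank-sum (Mann-Whitney) p-value for two samples of 0/1 values.

    Exact by enumeration for combined n <= 20, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    a_ones, b_ones = int(a.sum()), int(b.sum())
    if a.size + b.size <= EXACT_ENUMERATION_MAX_N:
        return _binary_ranksum_exact(a_ones, a.size, b_ones, b.size, alternative)
    return float(binary_ranksum_counts(a_ones, a.size, b_ones, b.size, alternative))


def _significant_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) column runs of a boolean mask."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_t1_response(raster: BinaryRaster, q: float = 0.05,
                       restrict_fastest_correct: bool = True,
                       fraction: float = 0.5) -> SamplewiseTest:
    """Per-sample comparison of each epoch column against the pooled
    pre-stimulus baseline, over the fastest correct trials.

    Two-sided (responses may be activations or suppressions); FDR across
    samples at ``q``; contiguous significant samples reported as segments.
    """
    values, trials = raster.values, raster.trials
    if restrict_fastest_correct:
        best = {t.trial_index for t in select_fastest_correct(trials, fraction)}
        rows = [i for i, t in enumerate(trials) if t.trial_index in best]
        values = values[rows]
    m = values.shape[0]
    if m < 10:
        raise ValueError(f"need >= 10 trials, have {m}")

    onset = raster.onset_column()
    base_cols = np.arange(onset - BASELINE_N_SAMPLES, onset)
    baseline = values[:, base_cols]
    b_ones, b_n = int(baseline.sum()), baseline.size

    n_cols = values.shape[1]
    if b_ones in (0, b_n):
        logger.warning("%s: degenerate baseline (all %d); p = 1 everywhere",
                       raster.site_label, int(b_ones > 0))
        p = np.ones(n_cols)
        direction = np.zeros(n_cols)
    else:
        col_ones = values.sum(axis=0).astype(float)
        p = binary_ranksum_counts(col_ones, m, b_ones, b_n, "two-sided")
        direction = np.sign(col_ones / m - b_ones / b_n)
    mask = multipletests(p, alpha=q, method="fdr_bh")[0] if np.any(p < 1) else np.zeros(n_cols, bool)
    return SamplewiseTest(site_label=raster.site_label, p_values=p, mask=mask,
                          direction=direction, q=q,
                          segments=_significant_segments(mask))


def pooled_on_percentage(binary: BinarySeries, windows) -> float:
    """On-percentage pooled over all samples of the given windows."""
    ones = total = 0
    for w in windows:
        i0 = sample_index(w.start, binary.rate)
        k = n_samples(w.length, binary.rate)
        seg = binary.values[i0:i0 + k]
        ones += int(seg.sum())
        total += seg.size
    if total == 0:
        raise ValueError("no samples in windows")
    return 100.0 * ones / total


def detect_t2_density(binary: BinarySeries, t2_windows, t2_free_windows,
                      n_surrogates: int = DEFAULT_N_SURROGATES,
                      n_sites: int = 1, alpha: float = 0.05,
                      seed: int | np.random.Generator = 0) -> SiteTestResult:
    """Is the on-state density in T2-windows abnormally high?

    The pooled on-percentage over the N T2-windows (PCT+) is compared to
    surrogate percentages from N randomly drawn T2-free windows; one-sided
    empirical p at a Bonferroni threshold alpha / n_sites.
    """
    n = len(t2_windows)
    if n < 1:
        raise ValueError("no T2-windows")
    if len(t2_free_windows) < n:
        raise ValueError("fewer T2-free windows than T2-windows")
    alpha_corr = alpha / n_sites
    if alpha_corr < 1.0 / (n_surrogates + 1):
        raise ValueError(
            f"surrogate granularity 1/{n_surrogates + 1} cannot resolve "
            f"Bonferroni threshold {alpha_corr:.2e}; raise n_surrogates")

    pct_plus = pooled_on_percentage(binary, t2_windows)
    counts = np.empty(len(t2_free_windows))
    sizes = np.empty(len(t2_free_windows))
    for i, w in enumerate(t2_free_windows):
        i0 = sample_index(w.start, binary.rate)
        k = n_samples(w.length, binary.rate)
        counts[i] = binary.values[i0:i0 + k].sum()
        sizes[i] = k
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.argsort(rng.random((n_surrogates, len(t2_free_windows))), axis=1)[:, :n]
    pct_minus = 100.0 * counts[draws].sum(axis=1) / sizes[draws].sum(axis=1)
    p = (1 + np.count_nonzero(pct_minus >= pct_plus)) / (1 + n_surrogates)
    return SiteTestResult(site_label=binary.site_label, pct_plus=pct_plus,
                          pct_minus=pct_minus, p=float(p),
                          alpha_corrected=alpha_corr,
                          significant=bool(p < alpha_corr), n_windows=n)


def interference_test(t2_densities, t1_best_densities, n_sites: int = 1,
                      alpha: float = 0.05, paired: bool = True,
                      site_label: str = "") -> InterferenceVerdict:
    """Signed-rank comparison of T2-window densities against densities
    around the fastest correct trials (one-sided: T2 denser).

    Pairing convention: the i-th chronological T2-window is paired with the
    window of the i-th fastest correct trial; an unpaired rank-sum variant
    is available with ``paired=False``.
    """
    t2 = np.array([d.density if isinstance(d, DensitySample) else d for d in t2_densities], float)
    t1 = np.array([d.density if isinstance(d, DensitySample) else d for d in t1_best_densities], float)
    if paired:
        if t2.size != t1.size:
            k = min(t2.size, t1.size)
            logger.warning("%s: unequal density lists (%d vs %d); pairing first %d",
                           site_label, t2.size, t1.size, k)
            t2, t1 = t2[:k], t1[:k]
    alpha_corr = alpha / n_sites
    if min(t2.size, t1.size) < 5:
        return InterferenceVerdict(site_label, t2, t1, np.nan, np.nan,
                                   alpha_corr, False, underpowered=True)
    if paired:
        diffs = t2 - t1
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = scipy.stats.wilcoxon(t2, t1, alternative="greater",
                                           zero_method="wilcox")
    else:
        stat, p = scipy.stats.mannwhitneyu(t2, t1, alternative="greater")
    return InterferenceVerdict(site_label, t2, t1, float(stat), float(p),
                               alpha_corr, bool(p < alpha_corr))


def _fastest_correct_rows(raster: BinaryRaster, m: int) -> np.ndarray:
    ranked = sorted(
        (i for i, t in enumerate(raster.trials) if t.correct and t.responded),
        key=lambda i: (raster.trials[i].response_time, raster.trials[i].trial_index))
    return raster.values[ranked[:m]]


def compare_st_dt(raster_st: BinaryRaster, raster_dt: BinaryRaster,
                  q: float = 0.05) -> SamplewiseTest:
    """Per-sample comparison of the M fastest correct trials of the ST and
    DT sessions, M = half the DT correct-trial count; two-sided, FDR at q."""
    n_correct_dt = sum(t.correct and t.responded for t in raster_dt.trials)
    m = n_correct_dt // 2
    underpowered = m < 10
    if underpowered:
        logger.warning("%s: only %d trials per group; ST/DT comparison underpowered",
                       raster_st.site_label, m)
    st = _fastest_correct_rows(raster_st, m)
    dt = _fastest_correct_rows(raster_dt, m)
    m_eff = min(st.shape[0], dt.shape[0])
    st, dt = st[:m_eff], dt[:m_eff]
    if m_eff == 0:
        raise ValueError("no correct trials to compare")
    p = binary_ranksum_counts(st.sum(axis=0).astype(float), m_eff,
                              dt.sum(axis=0).astype(float), m_eff, "two-sided")
    mask = multipletests(p, alpha=q, method="fdr_bh")[0] if np.any(p < 1) else np.zeros(p.size, bool)
    direction = np.sign(st.mean(axis=0) - dt.mean(axis=0))
    return SamplewiseTest(site_label=raster_st.site_label, p_values=p, mask=mask,
                          direction=direction, q=q,
                          segments=_significant_segments(mask),
                          underpowered=underpowered)


def automatization_test(raster: BinaryRaster,
                        window: tuple[float, float] = AUTOMATIZATION_WINDOW,
                        fraction: float = AUTOMATIZATION_FRACTION,
                        alpha: float = 0.05) -> TwoGroupResult:
    """Did per-trial density in a late epoch window drift between the first
    and last ``fraction`` of trials (chronological order)?  Two-sided
    rank-sum on per-trial densities."""
    n = len(raster.trials)
    k = int(np.floor(fraction * n))
    if k < 1 or 2 * k > n:
        raise ValueError(f"too few trials ({n}) for two groups of {fraction:.0%}")
    onset = raster.onset_column()
    c0 = onset + n_samples(window[0], raster.rate)
    c1 = onset + n_samples(window[1], raster.rate)
    chrono = np.argsort([t.trial_index for t in raster.trials])
    densities = raster.values[chrono, c0:c1].mean(axis=1)
    first, last = densities[:k], densities[-k:]
    if np.all(first == first[0]) and np.all(last == first[0]):
        stat, p = k * k / 2.0, 1.0
    else:
        stat, p = scipy.stats.mannwhitneyu(first, last, alternative="two-sided")
    return TwoGroupResult(site_label=raster.site_label, statistic=float(stat),
                          p=float(p), alpha=alpha, significant=bool(p < alpha),
                          group_means=(float(first.mean()), float(last.mean())))
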