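"""Behavioral dual-task cost statistics.

Two complementary analyses: a global single-task vs dual-task comparison of
reaction times and accuracy, and a within-dual-task randomization test
asking whether trials falling in the 2 s windows preceding overt verbal
responses (T2-windows) were slower or less accurate than trials in randomly
drawn response-free windows.

Conventions (documented, configurable where noted): a trial belongs to a
window iff its target onset lies in [start, end); reaction-time statistics
use correct responded trials only; accuracy counts misses as errors;
empirical p-values follow the (k + 1)/(n + 1) convention and are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .io_formats import TrialEvent
from .raster import AnalysisWindow

DEFAULT_N_SURROGATES = 10_000
DT_ALPHA = 0.01


@dataclass
class StDtResult:
    t_stat: float
    p_rt: float                 # one-sided: DT slower
    rt_mean_st: float
    rt_mean_dt: float
    accuracy_st: float
    accuracy_dt: float
    n_st: int
    n_dt: int


@dataclass
class BehaviorResult:
    rt_plus: float              # mean RT in T2-windows, s (nan if no trial)
    ac_plus: float              # fraction correct in T2-windows
    rt_minus: np.ndarray        # surrogate means, one per repeat
    ac_minus: np.ndarray
    p_rt: float
    p_acc: float
    n_windows: int
    n_surrogates: int
    alpha: float = DT_ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def rt_significant(self) -> bool:
        return self.p_rt < self.alpha

    @property
    def acc_significant(self) -> bool:
        return self.p_acc < self.alpha


def _rts(trials) -> np.ndarray:
    return np.array([t.response_time for t in trials if t.correct and t.responded])


def session_accuracy(trials: list[TrialEvent]) -> float:
    """Fraction of correct responses; misses count as errors."""
    if not trials:
        raise ValueError("no trials")
    return sum(t.correct for t in trials) / len(trials)


def st_dt_comparison(st_trials: list[TrialEvent], dt_trials: list[TrialEvent]) -> StDtResult:
    """Per-participant two-sample t-test on correct-trial RTs, one-sided in
    the direction of a dual-task slowing."""
    st, dt = _rts(st_trials), _rts(dt_trials)
    if st.size < 2 or dt.size < 2:
        raise ValueError("need >= 2 correct responded trials per session")
    if np.var(st, ddof=1) + np.var(dt, ddof=1) == 0:
        t_stat, p = 0.0, 0.5    # degenerate equal-constant samples
    else:
        t_stat, p = scipy.stats.ttest_ind(dt, st, alternative="greater")
    return StDtResult(t_stat=float(t_stat), p_rt=float(p),
                      rt_mean_st=float(st.mean()), rt_mean_dt=float(dt.mean()),
                      accuracy_st=session_accuracy(st_trials),
                      accuracy_dt=session_accuracy(dt_trials),
                      n_st=st.size, n_dt=dt.size)


def group_accuracy_test(acc_st: list[float], acc_dt: list[float]) -> tuple[float, float]:
    """Paired t-test across participants, one-sided (DT less accurate)."""
    a, b = np.asarray(acc_st, float), np.asarray(acc_dt, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need matched accuracy pairs from >= 2 participants")
    t, p = scipy.stats.ttest_rel(a, b, alternative="greater")
    return float(t), float(p)


def trials_in_windows(trials: list[TrialEvent],
                      windows: list[AnalysisWindow]) -> list[TrialEvent]:
    """Trials whose target onset falls in any of the given windows."""
    out = []
    for t in trials:
        if any(w.start <= t.target_onset < w.end for w in windows):
            out.append(t)
    return out


def _window_counts(trials, windows):
    """Per-window sufficient statistics: (sum RT, n responded-correct,
    n correct, n trials)."""
    stats = np.zeros((len(windows), 4))
    for t in trials:
        for i, w in enumerate(windows):
            if w.start <= t.target_onset < w.end:
                if t.correct and t.responded:
                    stats[i, 0] += t.response_time
                    stats[i, 1] += 1
                stats[i, 2] += t.correct
                stats[i, 3] += 1
                break
    return stats


def dt_window_randomization(trials: list[TrialEvent],
                            t2_windows: list[AnalysisWindow],
                            t2_free_windows: list[AnalysisWindow],
                            n_surrogates: int = DEFAULT_N_SURROGATES,
                            seed: int | np.random.Generator = 0,
                            alpha: float = DT_ALPHA) -> BehaviorResult:
    """Randomization test of the dual-task cost within the DT session.

    RT+/AC+ are computed over trials in the N T2-windows; each surrogate
    draws N T2-free windows without replacement and computes RT-/AC- over
    their pooled trials; p-values are one-sided (slower / less accurate),
    (k + 1)/(n + 1).
    """
    n = len(t2_windows)
    if n < 1:
        raise ValueError("no T2-windows")
    if len(t2_free_windows) < n:
        raise ValueError(f"need >= {n} T2-free windows, have {len(t2_free_windows)}")

    plus = _window_counts(trials, t2_windows).sum(axis=0)
    rt_plus = plus[0] / plus[1] if plus[1] else np.nan
    ac_plus = plus[2] / plus[3] if plus[3] else np.nan

    free_stats = _window_counts(trials, t2_free_windows)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # n_surrogates draws of n free windows each, without replacement per draw
    draws = np.argsort(rng.random((n_surrogates, len(t2_free_windows))), axis=1)[:, :n]
    pooled = free_stats[draws].sum(axis=1)          # (n_surrogates, 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        rt_minus = np.where(pooled[:, 1] > 0, pooled[:, 0] / pooled[:, 1], np.nan)
        ac_minus = np.where(pooled[:, 3] > 0, pooled[:, 2] / pooled[:, 3], np.nan)

    p_rt = (1 + np.count_nonzero(rt_minus >= rt_plus)) / (1 + n_surrogates)
    p_acc = (1 + np.count_nonzero(ac_minus <= ac_plus)) / (1 + n_surrogates)
    return BehaviorResult(rt_plus=float(rt_plus), ac_plus=float(ac_plus),
                          rt_minus=rt_minus, ac_minus=ac_minus,
                          p_rt=float(p_rt), p_acc=float(p_acc),
                          n_windows=n, n_surrogates=n_surrogates, alpha=alpha)
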