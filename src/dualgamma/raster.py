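"""Median-split binarization of HFA and the analysis windows built on it.

Vmed is the median HFA value over the pre-stimulus baselines (the 200 ms
before target onset) of the 50% fastest correct trials; every sample of the
session is then "on" iff its HFA strictly exceeds Vmed.  The three window
families drawn on the binarized series are:

* T2 windows — the 2 s preceding each overt verbal response (the only
  periods of certain secondary-task engagement);
* T2-free windows — a non-overlapping 2 s tiling of segments at least 2 s
  away from any verbal response (the surrogate pool);
* T1-best windows — [-800, 1,200) ms around the fastest correct trials
  (one attention-task cycle at peak performance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .hfa import BipolarSite, EpochMatrix, HfaSeries, epoch_hfa
from .io_formats import TrialEvent, VerbalEvent
from .timebase import n_samples, sample_index

logger = logging.getLogger(__name__)

BASELINE_WINDOW = (-0.2, 0.0)   # s relative to target onset
#: Samples per trial baseline at 64 Hz: the samples k/64 s before onset,
#: k = 1..12 (0.2 s x 64 Hz is not integral; strict half-open rule).
BASELINE_N_SAMPLES = 12
T2_WINDOW_S = 2.0
T2_FREE_MARGIN_S = 2.0
T1_BEST_WINDOW = (-0.8, 1.2)    # s relative to target onset
MISS_SORT_RT = 3.0              # s; misses sort as slowest incorrect


class WindowKind(str, Enum):
    T2 = "T2"
    T2_FREE = "T2_FREE"
    T1_BEST = "T1_BEST"


@dataclass(frozen=True)
class AnalysisWindow:
    kind: WindowKind
    start: float    # session s, inclusive
    end: float      # session s, exclusive
    anchor: object = None   # VerbalEvent or TrialEvent

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class VmedRecord:
    site_label: str
    session_id: str
    vmed: float
    n_baseline_samples: int
    n_trials_used: int


@dataclass
class BinarySeries:
    """Per-sample on/off states of one site at the analysis rate."""

    site_label: str
    session_id: str
    values: np.ndarray          # uint8 {0,1}
    rate: float
    vmed: VmedRecord | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.uint8)


@dataclass
class BinaryRaster:
    """Epoched binary matrix with display row order: incorrect trials
    (sorted by RT, misses last at RT = 3 s) above correct trials (by RT)."""

    site_label: str
    values: np.ndarray          # trials x samples {0,1}
    trials: list[TrialEvent]    # in row order
    window: tuple[float, float]
    rate: float
    session_id: str
    vmed: VmedRecord | None = None

    def onset_column(self) -> int:
        return -n_samples(self.window[0], self.rate)


@dataclass(frozen=True)
class DensitySample:
    window: AnalysisWindow
    density: float
    n_samples: int


# ---------------------------------------------------------------------------
# Vmed and binarization
# ---------------------------------------------------------------------------

def select_fastest_correct(trials: list[TrialEvent], fraction: float = 0.5) -> list[TrialEvent]:
    """The floor(fraction x n_correct) correct trials with the smallest RT;
    ties broken by trial index (earlier first)."""
    correct = [t for t in trials if t.correct and t.responded]
    if not correct:
        raise ValueError("no correct responded trials")
    k = int(np.floor(fraction * len(correct)))
    ranked = sorted(correct, key=lambda t: (t.response_time, t.trial_index))
    return ranked[:k]


def baseline_indices(trial: TrialEvent, rate: float) -> np.ndarray:
    """Indices of the pre-stimulus baseline samples of one trial."""
    onset = sample_index(trial.target_onset, rate)
    return np.arange(onset - BASELINE_N_SAMPLES, onset)


def compute_vmed(hfa: HfaSeries, best_trials: list[TrialEvent]) -> VmedRecord:
    """Median of the pooled baseline samples across the given trials."""
    pool = []
    for t in best_trials:
        idx = baseline_indices(t, hfa.rate)
        if idx[0] < 0 or idx[-1] >= hfa.n_samples:
            raise ValueError(f"trial {t.trial_index}: baseline outside session")
        pool.append(hfa.values[idx])
    if not pool:
        raise ValueError("empty baseline pool")
    pooled = np.concatenate(pool)
    return VmedRecord(site_label=hfa.site.label, session_id=hfa.session_id,
                      vmed=float(np.median(pooled)),
                      n_baseline_samples=pooled.size, n_trials_used=len(best_trials))


def binarize_series(hfa: HfaSeries, vmed: VmedRecord | float) -> BinarySeries:
    """on <=> value strictly greater than Vmed (equality is off)."""
    threshold = vmed.vmed if isinstance(vmed, VmedRecord) else float(vmed)
    if not np.isfinite(threshold):
        raise ValueError("Vmed must be finite")
    return BinarySeries(site_label=hfa.site.label, session_id=hfa.session_id,
                        values=(hfa.values > threshold).astype(np.uint8),
                        rate=hfa.rate,
                        vmed=vmed if isinstance(vmed, VmedRecord) else None)


def _display_sort_key(t: TrialEvent) -> tuple[int, float, int]:
    rt = t.response_time if t.responded else MISS_SORT_RT
    return (1 if t.correct else 0, rt, t.trial_index)


def build_raster(binary: BinarySeries, trials: list[TrialEvent],
                 window: tuple[float, float] = (-1.0, 3.0),
                 vmed: VmedRecord | None = None) -> BinaryRaster:
    """Epoched binary matrix in display order (incorrect block above correct
    block, each sorted by RT; misses count as incorrect at RT = 3 s)."""
    site = BipolarSite(binary.site_label, "", "", "")
    series = HfaSeries(site=site, values=binary.values.astype(float),
                       rate=binary.rate, session_id=binary.session_id, edge_trim=0.0)
    epochs: EpochMatrix = epoch_hfa(series, trials, window=window)
    order = sorted(range(len(epochs.trials)),
                   key=lambda i: _display_sort_key(epochs.trials[i]))
    return BinaryRaster(site_label=binary.site_label,
                        values=epochs.values[order].astype(np.uint8),
                        trials=[epochs.trials[i] for i in order],
                        window=window, rate=binary.rate,
                        session_id=binary.session_id,
                        vmed=vmed or binary.vmed)


# ---------------------------------------------------------------------------
# Analysis windows
# ---------------------------------------------------------------------------

def define_t2_windows(verbal: list[VerbalEvent],
                      length: float = T2_WINDOW_S) -> list[AnalysisWindow]:
    """One [onset - length, onset) window per verbal response; windows that
    would start before the session are dropped with a warning."""
    out = []
    for v in verbal:
        if v.onset < length:
            logger.warning("verbal response at %.3fs too early for a %.1fs window; dropped",
                           v.onset, length)
            continue
        out.append(AnalysisWindow(WindowKind.T2, v.onset - length, v.onset, anchor=v))
    return out


def define_t2_free_windows(verbal: list[VerbalEvent], session_span: float,
                           length: float = T2_WINDOW_S,
                           margin: float = T2_FREE_MARGIN_S) -> list[AnalysisWindow]:
    """Tile the response-free parts of the session with non-overlapping
    ``length``-s windows, staying ``margin`` s clear of every response.

    Maximal response-free segments are shrunk by ``margin`` at any end that
    abuts a response (session edges get no margin), tiled left to right, and
    remainders shorter than ``length`` discarded.
    """
    onsets = sorted(v.onset for v in verbal)
    bounds = [0.0] + onsets + [session_span]
    out: list[AnalysisWindow] = []
    for i in range(len(bounds) - 1):
        seg_start, seg_end = bounds[i], bounds[i + 1]
        if i > 0:                       # left end abuts a response
            seg_start += margin
        if i < len(bounds) - 2:         # right end abuts a response
            seg_end -= margin
        t = seg_start
        while t + length <= seg_end + 1e-9:
            out.append(AnalysisWindow(WindowKind.T2_FREE, t, t + length))
            t += length
    if not out:
        logger.warning("no response-free segment of >= %.1fs after margins; "
                       "empty T2-free window list", length)
    return out


def define_t1_best_windows(trials: list[TrialEvent], n: int,
                           window: tuple[float, float] = T1_BEST_WINDOW) -> list[AnalysisWindow]:
    """[-800, 1,200) ms windows around the n fastest correct target onsets."""
    correct = sorted((t for t in trials if t.correct and t.responded),
                     key=lambda t: (t.response_time, t.trial_index))
    if n > len(correct):
        logger.warning("requested %d fastest-correct windows but only %d correct trials",
                       n, len(correct))
        n = len(correct)
    return [AnalysisWindow(WindowKind.T1_BEST, t.target_onset + window[0],
                           t.target_onset + window[1], anchor=t)
            for t in correct[:n]]


def plot_raster(raster: BinaryRaster, ax=None, cmap: str = "Reds"):
    """Minimal display of a binary raster in its sorted row order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (raster.window[0] * 1000, raster.window[1] * 1000,
              raster.values.shape[0], 0)
    ax.imshow(raster.values, aspect="auto", interpolation="nearest",
              cmap=cmap, extent=extent)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time from target onset (ms)")
    ax.set_ylabel("trial (incorrect above, then correct; sorted by RT)")
    ax.set_title(raster.site_label)
    return ax


def window_on_density(binary: BinarySeries,
                      windows: list[AnalysisWindow]) -> list[DensitySample]:
    """Fraction of on-samples in each window (128 samples for a 2 s window)."""
    out = []
    for w in windows:
        i0 = sample_index(w.start, binary.rate)
        k = n_samples(w.length, binary.rate)
        if i0 < 0 or i0 + k > binary.values.size:
            raise ValueError(f"window [{w.start}, {w.end}) outside session")
        seg = binary.values[i0:i0 + k]
        out.append(DensitySample(window=w, density=float(seg.mean()), n_samples=k))
    return out
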