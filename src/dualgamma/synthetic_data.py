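"""Fully labeled synthetic dual-task sessions.

The generator emulates the statistical structure the analysis assumes, with
ground truth attached so every downstream detector can be validated:

* task schedule — trials of 200 ms target + 500 ms mask + array until the
  response (3,000 ms timeout) + 800 ms pause, balanced target-present /
  target-absent, 250 trials by default;
* behavior — log-normal reaction times and Bernoulli errors, both degraded
  inside "engagement windows" that each end at a verbal-response onset
  (covert engagement in the secondary task precedes the overt response by
  an unknown margin, modeled as 2-6 s);
* raw signal — per contact, 1/f background plus a band-limited 50-150 Hz
  carrier whose instantaneous amplitude follows the injected task-locked
  template, engagement gain, and shared latent envelope; optional 50 Hz
  line noise added equally to adjacent contacts so the bipolar derivation
  cancels it.

Everything is driven by one numpy Generator: the same seed reproduces the
schedule, behavior and signal bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (ElectrodeMap, Recording, TrialEvent, VerbalEvent,
                         parse_channel_label)

logger = logging.getLogger(__name__)


@dataclass
class BehaviorModel:
    """Log-normal RT and Bernoulli error model, with engagement penalties."""

    rt_log_mean: float = math.log(0.75)     # log-s; median baseline RT 750 ms
    rt_log_sd: float = 0.25
    rt_inflation: float = 1.5               # multiplies RT inside engagement windows
    error_prob: float = 0.05
    error_prob_engaged: float = 0.35


@dataclass
class EffectSpec:
    """Injected neural effects for one bipolar site.

    ``t1_kind`` selects the gain-vs-time template applied to the 50-150 Hz
    carrier amplitude around each target onset: "double_peak" (two transient
    activations) or "sustained" (plateau until the manual response).
    ``t2_gain`` multiplies the carrier amplitude inside engagement windows.
    Sites sharing a ``coupling_group`` are driven by one latent envelope
    with weight ``coupling_coef``.
    """

    site: str                               # bipolar label, e.g. "A1-A2"
    t1_kind: str = "none"                   # none | double_peak | sustained
    t1_amplitude: float = 0.0
    t2_gain: float = 0.0
    coupling_group: str | None = None
    coupling_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.t1_amplitude < 0 or self.t2_gain < 0:
            raise ValueError("gains must be >= 0")

    @property
    def flags(self) -> dict[str, bool]:
        return {"t1_responsive": self.t1_amplitude > 0,
                "t2_dense": self.t2_gain > 0,
                "interfering": self.t2_gain > 0}


@dataclass
class SimConfig:
    """All generator knobs; defaults are the study conditions."""

    n_trials: int = 250
    target_s: float = 0.2
    mask_s: float = 0.5
    max_array_s: float = 3.0
    pause_s: float = 0.8
    n_verbal: int = 16
    verbal_spacing_min_s: float = 8.0       # refractory gap so T2-free windows exist
    engagement_min_s: float = 2.0           # covert-engagement span before a response
    engagement_max_s: float = 6.0
    rate: float = 512.0
    pink_exponent: float = 1.0              # 1/f background slope
    carrier_std: float = 0.4                # band-limited carrier sd, rel. background sd 1
    effect_contrast: float = 1.0            # fraction of carrier kept by bipolar derivation
    line_amp: float = 0.0                   # 50 Hz sinusoid amplitude (common mode)
    line_freq: float = 50.0
    latent_cutoff_hz: float = 1.0           # bandwidth of shared latent envelopes
    latent_std: float = 0.5
    start_offset_s: float = 2.0             # first target onset
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_s", "mask_s", "max_array_s", "pause_s", "rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Labels the analysis is meant to recover."""

    site_flags: dict[str, dict[str, bool]]
    coupled_pairs: list[tuple[str, str, float]]
    behavior: BehaviorModel
    engagement_windows: list[tuple[float, float]]
    verbal_onsets: list[float]

    def __post_init__(self) -> None:
        ws = sorted(self.engagement_windows)
        for (a0, a1), (b0, b1) in zip(ws[:-1], ws[1:]):
            if b0 < a1:
                raise ValueError(f"engagement windows overlap: [{a0},{a1}) and [{b0},{b1})")
        ends = {round(w[1], 9) for w in self.engagement_windows}
        if not ends <= {round(v, 9) for v in self.verbal_onsets}:
            raise ValueError("every engagement window must end at a verbal onset")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Schedule and behavior
# ---------------------------------------------------------------------------

def _balanced_target_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    if n_trials % 2:
        raise ValueError("n_trials must be even to balance target-present/absent")
    seq = np.r_[np.ones(n_trials // 2, bool), np.zeros(n_trials // 2, bool)]
    return rng.permutation(seq)


def simulate_task_schedule(config: SimConfig,
                           seed: int | np.random.Generator | None = None,
                           rts: np.ndarray | None = None) -> list[TrialEvent]:
    """Trial timing only: onsets follow target + mask + (RT | timeout) + pause.

    RTs default to baseline log-normal draws; pass ``rts`` to fix them.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    present = _balanced_target_sequence(config.n_trials, rng)
    if rts is None:
        rts = rng.lognormal(config.behavior.rt_log_mean, config.behavior.rt_log_sd,
                            config.n_trials)
    trials = []
    onset = config.start_offset_s
    for i in range(config.n_trials):
        miss = rts[i] > config.max_array_s
        trials.append(TrialEvent(
            target_onset=onset, condition="ST", target_present=bool(present[i]),
            response_time=None if miss else float(rts[i]),
            correct=not miss, trial_index=i))
        array_time = config.max_array_s if miss else float(rts[i])
        onset += config.target_s + config.mask_s + array_time + config.pause_s
    return trials


def make_ground_truth(config: SimConfig, effects: list[EffectSpec],
                      seed: int | np.random.Generator = 0) -> GroundTruth:
    """Draw verbal onsets (refractory-spaced) and the engagement window
    preceding each, and collect the per-site flags."""
    rng = _as_rng(seed)
    b = config.behavior
    horizon = config.start_offset_s + config.n_trials * (
        config.target_s + config.mask_s + config.pause_s
        + math.exp(b.rt_log_mean + b.rt_log_sd ** 2 / 2))
    mean_gap = max(config.verbal_spacing_min_s + 1.0,
                   (horizon - 20.0) / max(config.n_verbal, 1))
    onsets, t = [], 10.0
    for _ in range(config.n_verbal):
        gap = config.verbal_spacing_min_s + rng.uniform(
            0.0, 2.0 * (mean_gap - config.verbal_spacing_min_s))
        t += gap
        onsets.append(t)
    windows = [(v - rng.uniform(config.engagement_min_s, config.engagement_max_s), v)
               for v in onsets]
    coupled: dict[str, list[EffectSpec]] = {}
    for e in effects:
        if e.coupling_group:
            coupled.setdefault(e.coupling_group, []).append(e)
    pairs = [(g[i].site, g[j].site, min(g[i].coupling_coef, g[j].coupling_coef))
             for g in coupled.values()
             for i in range(len(g)) for j in range(i + 1, len(g))]
    return GroundTruth(site_flags={e.site: e.flags for e in effects},
                       coupled_pairs=pairs, behavior=b,
                       engagement_windows=windows, verbal_onsets=onsets)


def _in_windows(t: float, windows: list[tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in windows)


def simulate_behavior(schedule: list[TrialEvent], ground_truth: GroundTruth,
                      condition: str, seed: int | np.random.Generator,
                      config: SimConfig) -> tuple[list[TrialEvent], list[VerbalEvent]]:
    """Assign RTs and correctness (re-timing onsets, since the array stays
    on screen until the response).

    Trials whose target onset falls inside an engagement window get their
    RT multiplied by the inflation factor and the raised error probability;
    drawn RTs beyond the 3 s timeout become misses.  For ST sessions there
    is no engagement and no verbal event.
    """
    rng = _as_rng(seed)
    b = ground_truth.behavior
    windows = ground_truth.engagement_windows if condition == "DT" else []
    trials = []
    onset = config.start_offset_s
    for i, proto in enumerate(schedule):
        engaged = _in_windows(onset, windows)
        rt = float(rng.lognormal(
            b.rt_log_mean + (math.log(b.rt_inflation) if engaged else 0.0),
            b.rt_log_sd))
        miss = rt > config.max_array_s
        p_err = b.error_prob_engaged if engaged else b.error_prob
        correct = (not miss) and (rng.random() >= p_err)
        trials.append(TrialEvent(
            target_onset=onset, condition=condition,
            target_present=proto.target_present,
            response_time=None if miss else rt, correct=correct, trial_index=i))
        onset += (config.target_s + config.mask_s
                  + (config.max_array_s if miss else rt) + config.pause_s)
    session_end = onset
    if condition != "DT":
        return trials, []
    verbals = [VerbalEvent(onset=v) for v in ground_truth.verbal_onsets
               if v <= session_end - 5.0]   # leave room for response-locked windows
    if len(verbals) < len(ground_truth.verbal_onsets):
        logger.info("dropped %d verbal event(s) beyond session end",
                    len(ground_truth.verbal_onsets) - len(verbals))
    return trials, verbals


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^exponent noise, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(n: int, rate: float, lo: float, hi: float,
                rng: np.random.Generator, edge: float = 2.0) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz
    (raised-cosine edges of ``edge`` Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = np.clip((freqs - (lo - edge)) / edge, 0, 1) * np.clip(((hi + edge) - freqs) / edge, 0, 1)
    mask = 0.5 - 0.5 * np.cos(np.pi * mask)  # smooth 0->1 transitions
    spec = mask * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _lowpass_noise(n: int, rate: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance slow Gaussian process (shared latent envelopes)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs <= cutoff).astype(float)
    mask[0] = 0.0
    spec = mask * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _template_gain(kind: str, amplitude: float, t: np.ndarray, rate: float,
                   trials: list[TrialEvent], max_array_s: float) -> np.ndarray:
    """Summed task-locked gain curve over the whole session."""
    gain = np.zeros(t.size)
    if kind == "none" or amplitude == 0.0:
        return gain
    for trial in trials:
        i0 = int(round(trial.target_onset * rate))
        if kind == "double_peak":
            n_t = int(round(1.0 * rate))
            tt = np.arange(n_t) / rate
            curve = amplitude * (np.exp(-((tt - 0.15) / 0.05) ** 2)
                                 + np.exp(-((tt - 0.45) / 0.08) ** 2))
        elif kind == "sustained":
            rt = trial.response_time if trial.responded else max_array_s
            n_t = int(round(min(rt + 0.2, max_array_s) * rate))
            curve = np.zeros(n_t)
            curve[int(round(0.1 * rate)):] = amplitude
        else:
            raise ValueError(f"unknown template kind {kind!r}")
        i1 = min(i0 + curve.size, t.size)
        if i0 < t.size:
            gain[i0:i1] += curve[:i1 - i0]
    return gain


def _site_channels(site_label: str) -> tuple[tuple[str, str, int], tuple[str, str, int]]:
    a, b = site_label.split("-")
    ea, ca = parse_channel_label(a)
    eb, cb = parse_channel_label(b)
    if ea != eb or abs(ca - cb) != 1:
        raise ValueError(f"site {site_label!r} is not an adjacent contact pair")
    return (a, ea, ca), (b, eb, cb)


def simulate_recording(schedule: list[TrialEvent], verbal_events: list[VerbalEvent],
                       effects: list[EffectSpec], config: SimConfig,
                       seed: int | np.random.Generator,
                       ground_truth: GroundTruth | None = None,
                       session_id: str = "ST") -> Recording:
    """Synthesize the raw monopolar signal matrix (two contacts per site).

    Per contact: 1/f background + amplitude-modulated 50-150 Hz carrier
    (+ common-mode line noise).  The carrier is added to the first contact
    at full weight and to the second at ``1 - effect_contrast``, so the
    bipolar derivation keeps the injected effect at the configured contrast
    while the line sinusoid cancels exactly.
    """
    rng = _as_rng(seed)
    end = schedule[-1].target_onset + config.max_array_s + config.pause_s
    if verbal_events:
        end = max(end, max(v.onset for v in verbal_events) + 5.0)
    duration = int(math.ceil(end + 2.0))
    n = int(duration * config.rate)
    t = np.arange(n) / config.rate

    windows = (ground_truth.engagement_windows if ground_truth is not None
               else [(v.onset - config.engagement_min_s, v.onset) for v in verbal_events])
    engaged = np.zeros(n)
    for a, b in windows:
        engaged[max(0, int(a * config.rate)):max(0, int(b * config.rate))] = 1.0

    latents: dict[str, np.ndarray] = {}
    for e in effects:
        if e.coupling_group and e.coupling_group not in latents:
            latents[e.coupling_group] = _lowpass_noise(n, config.rate,
                                                       config.latent_cutoff_hz, rng)

    line = (config.line_amp * np.sin(2 * np.pi * config.line_freq * t)
            if config.line_amp else 0.0)

    signals, channels = [], []
    for e in effects:
        (lab_a, elec, ca), (lab_b, _, cb) = _site_channels(e.site)
        gain = 1.0 + _template_gain(e.t1_kind, e.t1_amplitude, t, config.rate,
                                    schedule, config.max_array_s)
        gain *= 1.0 + e.t2_gain * engaged
        if e.coupling_group:
            gain *= np.maximum(
                1.0 + e.coupling_coef * config.latent_std * latents[e.coupling_group], 0.05)
        carrier = config.carrier_std * _band_noise(n, config.rate, 50.0, 150.0, rng) * gain
        contact_a = _pink_noise(n, config.pink_exponent, rng) + carrier + line
        contact_b = (_pink_noise(n, config.pink_exponent, rng)
                     + (1.0 - config.effect_contrast) * carrier + line)
        signals += [contact_a, contact_b]
        channels += [(lab_a, elec, ca), (lab_b, elec, cb)]

    return Recording(signal=np.vstack(signals), rate=config.rate,
                     channels=channels, session_id=session_id)


# ---------------------------------------------------------------------------
# Ground-truth round trip
# ---------------------------------------------------------------------------

def emit_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    payload = dataclasses.asdict(gt)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return Path(path)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        site_flags={k: dict(v) for k, v in d["site_flags"].items()},
        coupled_pairs=[tuple(p) for p in d["coupled_pairs"]],
        behavior=BehaviorModel(**d["behavior"]),
        engagement_windows=[tuple(w) for w in d["engagement_windows"]],
        verbal_onsets=list(d["verbal_onsets"]))


# ---------------------------------------------------------------------------
# Canonical scenario
# ---------------------------------------------------------------------------

@dataclass
class Session:
    recording: Recording
    trials: list[TrialEvent]
    verbals: list[VerbalEvent]
    ground_truth: GroundTruth
    electrodes: ElectrodeMap
    condition: str


#: Desk-scale eight-site scenario: three interfering sites (sustained
#: task response plus engagement gain; two of them coupled), three sites
#: with a transient task response only, two null sites.
def default_effects() -> list[EffectSpec]:
    return [
        EffectSpec("A1-A2", "sustained", 0.8, 2.0, coupling_group="g1", coupling_coef=0.8),
        EffectSpec("B1-B2", "sustained", 0.8, 2.0, coupling_group="g1", coupling_coef=0.8),
        EffectSpec("C1-C2", "sustained", 0.8, 2.0),
        EffectSpec("D1-D2", "double_peak", 1.5, 0.0),
        EffectSpec("E1-E2", "double_peak", 1.5, 0.0),
        EffectSpec("F1-F2", "double_peak", 1.5, 0.0),
        EffectSpec("G1-G2"),
        EffectSpec("H1-H2"),
    ]


_ELECTRODE_POSITIONS = {
    "A": (-50.0, 10.0, 20.0), "B": (48.0, 12.0, 22.0), "C": (-8.0, -62.0, 10.0),
    "D": (-4.0, 55.0, 12.0), "E": (-42.0, -40.0, -18.0), "F": (40.0, 42.0, -20.0),
    "G": (-38.0, 44.0, 42.0), "H": (36.0, -46.0, 44.0),
}


def default_electrode_map(effects: list[EffectSpec]) -> ElectrodeMap:
    coords = {}
    for e in effects:
        (lab_a, elec, _), (lab_b, _, _) = _site_channels(e.site)
        base = np.array(_ELECTRODE_POSITIONS.get(elec, (0.0, 0.0, 0.0)))
        coords[lab_a] = base
        coords[lab_b] = base + np.array([3.5, 0.0, 0.0])  # 3.5 mm contact spacing
    return ElectrodeMap(coords)


def simulate_session(config: SimConfig, effects: list[EffectSpec], condition: str,
                     seed: int | np.random.Generator | None = None) -> Session:
    """Schedule -> behavior -> raw signal, with ground truth attached."""
    rng = _as_rng(config.seed if seed is None else seed)
    gt = make_ground_truth(config, effects, rng)
    schedule = simulate_task_schedule(config, rng)
    trials, verbals = simulate_behavior(schedule, gt, condition, rng, config)
    rec = simulate_recording(trials, verbals, effects, config, rng,
                             ground_truth=gt, session_id=condition)
    if condition != "DT":
        gt = dataclasses.replace(gt, engagement_windows=[], verbal_onsets=[])
    return Session(recording=rec, trials=trials, verbals=verbals, ground_truth=gt,
                   electrodes=default_electrode_map(effects), condition=condition)
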