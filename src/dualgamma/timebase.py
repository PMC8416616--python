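"""Session-time <-> sample-index conventions shared across the pipeline.

All session times are seconds (floats); all analysis windows are half-open
[start, end).  At the analysis rate (64 Hz) a window is realized as the run
of samples ``round(start * rate) + [0, round(length * rate))`` so that every
2 s window holds exactly 128 samples and the 4 s epoch exactly 256.
"""

from __future__ import annotations

import numpy as np

#: Analysis rate of the normalized high-frequency-activity series, Hz.
HFA_RATE = 64.0


def sample_index(t: float, rate: float = HFA_RATE) -> int:
    """Index of the sample representing session time ``t`` (round to nearest)."""
    return int(np.round(t * rate))


def n_samples(length: float, rate: float = HFA_RATE) -> int:
    """Number of samples in a window of ``length`` seconds."""
    return int(np.round(length * rate))


def window_indices(start: float, length: float, rate: float = HFA_RATE) -> np.ndarray:
    """Sample indices covering the half-open window [start, start+length)."""
    i0 = sample_index(start, rate)
    return np.arange(i0, i0 + n_samples(length, rate))
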