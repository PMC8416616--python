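import numpy as np
import pytest

from dualgamma.io_formats import TrialEvent
from dualgamma.synthetic_data import SimConfig, Session, default_effects, simulate_session


@pytest.fixture(scope="session")
def small_dt_session() -> Session:
    """A desk-scale dual-task session with the canonical 8-site effect set."""
    cfg = SimConfig(n_trials=60, n_verbal=12, seed=7)
    return simulate_session(cfg, default_effects(), "DT", 7)


@pytest.fixture(scope="session")
def small_st_session() -> Session:
    cfg = SimConfig(n_trials=60, n_verbal=12, seed=7)
    return simulate_session(cfg, default_effects(), "ST", 11)


def make_trials(rts, correct=None, start=2.0, gap=2.5, condition="ST"):
    """Evenly spaced trials with the given RTs (None = miss)."""
    correct = correct if correct is not None else [rt is not None for rt in rts]
    return [TrialEvent(target_onset=start + i * gap, condition=condition,
                       target_present=bool(i % 2), response_time=rts[i],
                       correct=bool(correct[i]) and rts[i] is not None,
                       trial_index=i)
            for i in range(len(rts))]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
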