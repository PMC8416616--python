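"""Pipeline configuration: one YAML/JSON file drives every stage.

Defaults are the analysis constants: 50-150 Hz band in 10 Hz sub-bands at a
64 Hz output rate, 2,000 ms T2-windows, the 50% fastest correct trials as
baseline, 10,000 surrogates, samplewise alpha 0.05 and behavioral alpha
0.01, [-800, 1,200) ms task windows, [-1,000, 3,000) ms epochs,
[-6,000, 4,000) ms correlation windows, a 30 mm surrogate distance floor
and 20% trial blocks for the automatization check.  Unknown keys are an
error so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_data import BehaviorModel, SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    band: tuple[float, float] = (50.0, 150.0)
    subband_width: float = 10.0
    hfa_rate: float = 64.0
    epoch_window: tuple[float, float] = (-1.0, 3.0)        # s around target onset
    t2_window_s: float = 2.0
    t2_free_margin_s: float = 2.0
    t1_best_window: tuple[float, float] = (-0.8, 1.2)      # s around target onset
    fastest_fraction: float = 0.5
    n_surrogates: int = 10_000
    alpha_samplewise: float = 0.05
    alpha_behavior: float = 0.01
    alpha_sites: float = 0.05
    correlation_window: tuple[float, float] = (-6.0, 4.0)  # s around verbal onset
    min_surrogate_distance_mm: float = 30.0
    automatization_fraction: float = 0.2
    automatization_window: tuple[float, float] = (0.9, 1.2)
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if f.name == "sim":
            value = _build(SimConfig, value or {}, f"{path}.sim")
        elif f.name == "behavior":
            value = _build(BehaviorModel, value or {}, f"{path}.behavior")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Read a YAML (or JSON) config; absent keys take the defaults above."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    data = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    return _build(PipelineConfig, data or {}, str(path))
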