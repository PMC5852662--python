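"""Pipeline configuration: one structured object, serialized as YAML.

Numeric defaults follow the analysis settings the pipeline is built around:
1500 ms press guard, 55-epoch minimum cell count, 1000 permutations at
alpha 0.05, 5 folds x 100 repeats with C = 1, the 216-288 ms window, and
resampling to 250 Hz.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic_data import NeuralParams, PerceptParams


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 23
    n_blocks: int = 4
    n_triplets: int = 250
    h_freq: float = 1017.0
    percept: PerceptParams = field(default_factory=PerceptParams)
    neural: NeuralParams = field(default_factory=NeuralParams)
    lowpass_hz: float = 30.0
    lowpass_transition_hz: float = 6.667
    highpass_hz: float = 0.278
    highpass_transition_hz: float = 0.556
    resample_hz: float = 250.0
    guard_s: float = 1.5
    min_cell: int = 55
    exclude_before_first_segregated: bool = False
    n_perm: int = 1000
    alpha: float = 0.05
    window_s: tuple[float, float] = (0.216, 0.288)
    folds: int = 5
    repeats: int = 100
    C: float = 1.0
    svm_solver: str = "liblinear"
    compute_patterns: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("folds must be >= 2 and repeats >= 1")
        if self.n_participants < 1 or self.n_blocks < 1 or self.n_triplets < 1:
            raise ValueError("cohort sizes must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_s"] = list(self.window_s)
        d["neural"]["kernel_amplitudes"] = list(self.neural.kernel_amplitudes)
        d["neural"]["segregation_window"] = list(self.neural.segregation_window)
        d["neural"]["noise_band"] = list(self.neural.noise_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "percept" in d and isinstance(d["percept"], dict):
            d["percept"] = PerceptParams(**d["percept"])
        if "neural" in d and isinstance(d["neural"], dict):
            nd = dict(d["neural"])
            for key in ("kernel_amplitudes", "segregation_window", "noise_band"):
                if key in nd:
                    nd[key] = tuple(nd[key])
            d["neural"] = NeuralParams(**nd)
        if "window_s" in d:
            d["window_s"] = tuple(d["window_s"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
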