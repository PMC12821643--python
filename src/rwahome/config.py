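"""Run configuration: every pipeline parameter in one validated object.

Defaults equal the recording-device and scoring-rule constants: 128 Hz
sampling, 30-s epochs, 3-s mini-epochs, 4x amplitude threshold, 0.1-5 s
phasic burst duration, >50% mini-epoch occupancy, >=1 active mini-epoch
per RWA epoch, 0% patient positivity cutoff, mean-of-nights aggregation.
Configs load from YAML; unknown keys are rejected at load time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synth import SimulationConfig, _default_stage_params


@dataclass
class RunConfig:
    # simulation
    sampling_rate: float = 128.0
    epoch_len: float = 30.0
    night_len_min: float = 480.0
    background_amp: float = 10.0
    stage_params: dict = field(default_factory=_default_stage_params)
    # scoring
    band_low: float = 10.0
    band_high: float | None = None  # None: 90% of Nyquist
    smooth_s: float = 0.05
    envelope_method: str = "hilbert"
    background_scope: str = "rem"
    trim_top: float = 0.10
    amplitude_ratio: float = 4.0
    min_burst_s: float = 0.1
    max_burst_s: float = 5.0
    mini_len: float = 3.0
    min_active_mini: int = 1
    patient_cutoff_pct: float = 0.0
    night_aggregation: str = "mean"
    # statistics
    contingency_method: str = "fisher"
    mw_method: str = "auto"
    holm: bool = False
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.night_len_min <= 0:
            raise ValueError("sampling_rate and night_len_min must be positive")
        if self.epoch_len % self.mini_len != 0:
            raise ValueError("mini_len must divide epoch_len")
        if self.amplitude_ratio <= 0 or self.min_burst_s <= 0:
            raise ValueError("amplitude_ratio and min_burst_s must be positive")
        if self.max_burst_s < self.min_burst_s:
            raise ValueError("max_burst_s must be >= min_burst_s")
        if self.night_aggregation not in ("mean", "max"):
            raise ValueError("night_aggregation must be 'mean' or 'max'")
        if self.contingency_method not in ("fisher", "chi2"):
            raise ValueError("contingency_method must be 'fisher' or 'chi2'")
        if not 1 <= self.min_active_mini <= int(self.epoch_len // self.mini_len):
            raise ValueError("min_active_mini outside the per-epoch mini count")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            sampling_rate=self.sampling_rate,
            epoch_len=self.epoch_len,
            night_len_min=self.night_len_min,
            background_amp=self.background_amp,
            stage_params=self.stage_params,
            seed=self.seed if seed is None else seed,
        )
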