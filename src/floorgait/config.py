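"""Pipeline configuration: one YAML-loadable object covering every stage.

Defaults reflect the study conditions the simulator emulates: a 500 Hz
lab sampling rate (97% of footstep power sits below 250 Hz, so higher
hospital rates are downsampled before feature extraction), a 5-25 Hz
floor-resonance band, and the printed network widths 12/256/64,
20/128/32 and 9/64.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import RecoveryConfig
from .hierarchy import ModelConfig
from .synthetic import FloorModel, SensorLayout

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated bundle of generator, detection and model parameters."""

    seed: int = 0
    n_subjects: int = 12
    stage_distribution: tuple[float, ...] = (1 / 6,) * 6
    traces_per_subject: tuple[int, int] = (5, 10)
    n_steps_range: tuple[int, int] = (8, 12)
    noise_sd: float = 0.02
    sampling_rate: float = 500.0
    sensor_positions: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    natural_frequency: float = 15.0
    damping_ratio: float = 0.25
    attenuation_rate: float = 0.35
    wavelet_band: tuple[float, float] = (5.0, 25.0)
    min_separation_s: float = 0.25
    prominence_factor: float = 3.0
    contact_examples_per_class: int = 60
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.wavelet_band[0] < self.wavelet_band[1]:
            raise ValueError("wavelet_band must be an increasing positive pair")
        # these construct-and-validate via their own invariants
        self.layout()
        self.floor()

    def layout(self) -> SensorLayout:
        return SensorLayout(
            positions=tuple(self.sensor_positions), sampling_rate=self.sampling_rate
        )

    def floor(self) -> FloorModel:
        return FloorModel(
            natural_frequency=self.natural_frequency,
            damping_ratio=self.damping_ratio,
            attenuation_rate=self.attenuation_rate,
        )

    def recovery(self) -> RecoveryConfig:
        return RecoveryConfig(
            n_subjects=self.n_subjects,
            stage_distribution=tuple(self.stage_distribution),
            traces_per_subject=tuple(self.traces_per_subject),
            n_steps_range=tuple(self.n_steps_range),
            noise_sd=self.noise_sd,
            contact_examples_per_class=self.contact_examples_per_class,
            layout=self.layout(),
            floor=self.floor(),
            model=self.model,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Stable digest embedded in outputs for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (optional) and apply keyword overrides.

    Unknown keys raise a schema error before any stage runs.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    model_raw = raw.pop("model", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stage_distribution", "traces_per_subject", "n_steps_range",
                "sensor_positions", "wavelet_band"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if model_raw is not None:
        model_known = {f.name for f in dataclasses.fields(ModelConfig)}
        bad = set(model_raw) - model_known
        if bad:
            raise ValueError(f"unknown model config keys: {sorted(bad)}")
        for key in ("step_widths", "trace_widths", "person_widths"):
            if key in model_raw:
                model_raw[key] = tuple(model_raw[key])
        raw["model"] = ModelConfig(**model_raw)
    return PipelineConfig(**raw)
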