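"""Core data containers shared across the floor-vibration gait pipeline.

A *recording* is one geophone's voltage time series for a single walking
pass ("trace"); a *footstep impulse* is a segmented transient within it.
All times are seconds from the start of the recording; intervals are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorRecording",
    "FootstepImpulse",
    "Biometrics",
    "GroundTruthAnnotations",
    "WalkTrace",
    "SubjectData",
]


@dataclass
class SensorRecording:
    """One sensor's voltage time series.

    Parameters
    ----------
    samples
        Voltage series (volts, arbitrary reference).
    sampling_rate
        Samples per second.
    sensor_id
        Integer sensor label (enters the step-level feature vector, since
        floor heterogeneity makes the response sensor-dependent).
    noise_reference
        ``(start, stop)`` sample indices of a footstep-free segment used
        to estimate the ambient noise statistics.
    position
        Sensor position along the walkway in meters, if known.
    distractor_intervals
        ``(onset_s, offset_s, kind)`` log of injected non-footstep
        transients, kept so detection filters can be scored.
    """

    samples: np.ndarray
    sampling_rate: float
    sensor_id: int = 0
    noise_reference: tuple[int, int] | None = None
    position: float | None = None
    distractor_intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_reference is not None:
            a, b = self.noise_reference
            if not (0 <= a < b <= self.samples.size):
                raise ValueError("noise_reference out of bounds or empty")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class FootstepImpulse:
    """A segmented footstep-induced transient."""

    onset_time: float
    offset_time: float
    samples: np.ndarray
    sampling_rate: float
    sensor_id: int = 0
    index_in_trace: int = 1
    clipped: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.onset_time < self.offset_time:
            raise ValueError("onset must precede offset")

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass(frozen=True)
class Biometrics:
    """Subject biometrics used as normative covariates and model inputs."""

    age: float  # years
    weight: float  # kg
    height: float  # m
    gender: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.age <= 0 or self.weight <= 0 or self.height <= 0:
            raise ValueError("age, weight and height must be positive")

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2 (the covariate form of the normative model)."""
        return self.weight / self.height**2


@dataclass
class GroundTruthAnnotations:
    """Simulator oracle: per-footstep ground truth for one walking trace."""

    strike_times: np.ndarray  # s, strictly increasing
    contact_types: list[str]  # heel | midfoot | toe, one per footstep
    peak_forces: np.ndarray  # dimensionless force scale per footstep
    stage_label: int  # functional stage 0-5
    biometrics: Biometrics | None = None

    def __post_init__(self) -> None:
        self.strike_times = np.asarray(self.strike_times, dtype=float)
        self.peak_forces = np.asarray(self.peak_forces, dtype=float)
        if self.strike_times.size and np.any(np.diff(self.strike_times) <= 0):
            raise ValueError("strike_times must be strictly increasing")
        if len(self.contact_types) != self.strike_times.size:
            raise ValueError("one contact type per footstep required")

    @property
    def n_steps(self) -> int:
        return int(self.strike_times.size)


@dataclass
class WalkTrace:
    """One walking pass: one recording per sensor plus the oracle annotations."""

    recordings: list[SensorRecording]
    annotations: GroundTruthAnnotations


@dataclass
class SubjectData:
    """One simulated subject: biometrics, 100-m run time, stage, traces."""

    subject_id: int
    biometrics: Biometrics
    run_time_100m: float  # s
    stage: int
    traces: list[WalkTrace]
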