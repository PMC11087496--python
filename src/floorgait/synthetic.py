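"""Synthetic floor-vibration gait simulator with ground-truth annotations.

Emulates the statistical structure of footstep-induced floor vibration as
seen by geophones along a walkway:

* each footstep is a short (0.2-0.6 s) transient: a damped oscillation at
  the floor's natural frequency (5-25 Hz band) plus a contact burst whose
  dominant frequency depends on the initial-contact type (heel < midfoot
  < toe, reflecting smaller contact area / more frictional content);
* the walker moves along the walkway, so each sensor sees amplitudes
  attenuated by its distance to the current footstep position;
* left-right force asymmetry scales alternating steps;
* disease stage shifts cadence (up then down), toe-contact probability
  (up) and symmetry (down);
* ambient Gaussian noise rides on everything, and a leading pure-noise
  segment is reserved for noise-reference estimation.

Non-footstep distractor transients (door-slam-like isolated impulses,
over-long transients, sub-0.2 s blips) can be superimposed with their
intervals logged, so the detection filters can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    Biometrics,
    GroundTruthAnnotations,
    SensorRecording,
    SubjectData,
    WalkTrace,
)
from .scale import STAGE_LOWER_BOUNDS

__all__ = [
    "FloorModel",
    "GaitProfile",
    "SensorLayout",
    "CONTACT_TYPES",
    "CONTACT_BURST_FREQS",
    "generate_footstep_pulse",
    "gait_profile_for_stage",
    "generate_walk_trace",
    "inject_distractors",
    "generate_cohort",
]

CONTACT_TYPES = ("heel", "midfoot", "toe")

# Contact-burst dominant frequencies (Hz). The ordering heel < midfoot < toe
# encodes the smaller contact surface and stronger frictional content of
# forefoot strikes; the absolute values are generator conventions exposed
# here as configuration. A heel strike's large, soft contact mainly excites
# the floor resonance itself, so its "burst" is the resonance (no separate
# component); midfoot and toe add a higher-frequency frictional burst.
CONTACT_BURST_FREQS: dict[str, float] = {"heel": 15.0, "midfoot": 60.0, "toe": 120.0}
_BURST_AMPLITUDE: dict[str, float] = {"heel": 0.0, "midfoot": 2.0, "toe": 2.0}

LEAD_NOISE_S = 2.5  # leading footstep-free segment, > 2 s
NOISE_REF_S = 2.0  # portion of the lead marked as noise reference


@dataclass(frozen=True)
class FloorModel:
    """Lumped floor response: resonance band, damping, geometric attenuation."""

    natural_frequency: float = 15.0  # Hz, within the typical 5-25 Hz band
    damping_ratio: float = 0.25  # dimensionless, in (0, 1)
    attenuation_rate: float = 0.35  # per-meter amplitude decay, >= 0

    def __post_init__(self) -> None:
        if not 5.0 <= self.natural_frequency <= 25.0:
            raise ValueError("natural_frequency must lie in the 5-25 Hz floor band")
        if not 0.0 < self.damping_ratio < 1.0:
            raise ValueError("damping_ratio must be in (0, 1)")
        if self.attenuation_rate < 0:
            raise ValueError("attenuation_rate must be non-negative")

    def attenuation(self, distance_m: float | np.ndarray) -> float | np.ndarray:
        """Amplitude decay factor at a given source-sensor distance."""
        return np.exp(-self.attenuation_rate * np.abs(distance_m))


@dataclass(frozen=True)
class GaitProfile:
    """Per-subject gait parameterization driving the simulator."""

    cadence: float  # steps/min
    step_time_jitter_sd: float  # s
    left_right_amplitude_ratio: float  # strong/weak side force ratio, > 0
    contact_type_probs: tuple[float, float, float]  # (heel, midfoot, toe)
    force_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.step_time_jitter_sd < 0:
            raise ValueError("step_time_jitter_sd must be non-negative")
        if self.left_right_amplitude_ratio <= 0:
            raise ValueError("left_right_amplitude_ratio must be positive")
        if self.force_scale <= 0:
            raise ValueError("force_scale must be positive")
        p = np.asarray(self.contact_type_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("contact_type_probs must be a simplex over 3 types")

    @property
    def mean_step_time(self) -> float:
        """Mean inter-strike interval in seconds (reciprocal of cadence)."""
        return 60.0 / self.cadence


@dataclass(frozen=True)
class SensorLayout:
    """Sensor positions (m, strictly increasing) and sampling rate (Hz)."""

    positions: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        if len(self.positions) == 0:
            raise ValueError("layout must contain at least one sensor")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("sensor positions must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_footstep_pulse(
    contact_type: str,
    force_scale: float,
    floor: FloorModel,
    sampling_rate: float,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one footstep transient.

    The waveform is a rapidly attacking, damped oscillation at the floor's
    natural frequency plus a shorter contact burst at the contact-type
    frequency; a raised-cosine tail brings it to exactly zero, keeping the
    duration inside [0.2, 0.6] s. ``force_scale = 0`` yields silence.
    """
    if contact_type not in CONTACT_TYPES:
        raise ValueError(f"unknown contact_type {contact_type!r}")
    rng = _as_rng(rng_seed)
    duration = float(rng.uniform(0.35, 0.55))
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    # rapid attack, then a sustained stance-phase release: the foot loads
    # the floor for the better part of the contact, so the transient stays
    # well above ambient noise for 0.2-0.4 s before dying out
    attack = 1.0 - np.exp(-t / 0.008)
    sustain = np.exp(-((t / 0.18) ** 2))
    envelope = attack * sustain

    omega_d = (
        2.0 * np.pi * floor.natural_frequency * np.sqrt(1.0 - floor.damping_ratio**2)
    )
    resonance = 1.5 * envelope * np.sin(omega_d * t)
    f_burst = CONTACT_BURST_FREQS[contact_type]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    burst = (
        _BURST_AMPLITUDE[contact_type]
        * envelope
        * np.sin(2.0 * np.pi * f_burst * t + phase)
    )

    pulse = resonance + burst
    taper_n = max(int(0.05 * sampling_rate), 2)
    taper = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, taper_n)))
    pulse[-taper_n:] *= taper
    # peak-normalize so amplitude encodes force (and attenuation), not
    # contact type: the same leg delivers a similar peak force whichever
    # part of the foot lands first
    peak = float(np.max(np.abs(pulse)))
    if peak > 0:
        pulse = pulse / peak
    return force_scale * pulse


# Stage-conditioned gait parameter tables (stage 0 = healthy .. 5 = late
# ambulatory). Cadence rises through the heel->toe transition then falls
# with muscle degeneration; toe-contact probability rises monotonically;
# the left-right force ratio departs from 1 monotonically so the symmetry
# score falls in expectation; step-time jitter grows with instability.
_CADENCE_BY_STAGE = (105.0, 112.0, 118.0, 112.0, 100.0, 88.0)
_TOE_P_BY_STAGE = (0.03, 0.12, 0.28, 0.45, 0.62, 0.80)
_HEEL_P_BY_STAGE = (0.85, 0.64, 0.44, 0.29, 0.18, 0.08)
_LR_RATIO_BY_STAGE = (1.0, 1.12, 1.25, 1.40, 1.60, 1.85)
_JITTER_SD_BY_STAGE = tuple(0.010 + 0.006 * s for s in range(6))


def gait_profile_for_stage(
    stage: int, rng_seed: int | np.random.Generator | None = None
) -> GaitProfile:
    """Draw a gait profile consistent with a functional stage 0-5.

    Per-subject jitter is small relative to the between-stage spacing, so
    toe-contact probability is non-decreasing and the left-right ratio's
    departure from 1 non-decreasing across stages for every draw; stage 0
    is exactly symmetric.
    """
    if stage not in range(6):
        raise ValueError("stage must be an integer in 0..5")
    rng = _as_rng(rng_seed)
    cadence = _CADENCE_BY_STAGE[stage] + rng.normal(0.0, 2.0)
    toe_p = float(np.clip(_TOE_P_BY_STAGE[stage] + rng.uniform(-0.02, 0.02), 0.0, 1.0))
    heel_p = float(np.clip(_HEEL_P_BY_STAGE[stage] + rng.uniform(-0.02, 0.02), 0.0, 1.0 - toe_p))
    mid_p = 1.0 - heel_p - toe_p
    ratio = _LR_RATIO_BY_STAGE[stage] + stage * rng.uniform(-0.01, 0.01)
    return GaitProfile(
        cadence=float(cadence),
        step_time_jitter_sd=_JITTER_SD_BY_STAGE[stage],
        left_right_amplitude_ratio=float(ratio),
        contact_type_probs=(heel_p, mid_p, toe_p),
        force_scale=float(1.0 + rng.uniform(-0.1, 0.1)),
    )


def generate_walk_trace(
    profile: GaitProfile,
    n_steps: int,
    layout: SensorLayout,
    floor: FloorModel,
    noise_sd: float,
    rng_seed: int | np.random.Generator | None = None,
    stage_label: int = 0,
    biometrics: Biometrics | None = None,
    step_length: float = 0.6,
) -> WalkTrace:
    """Simulate one walking pass over the sensor layout.

    Strike intervals are Normal(60/cadence, jitter); alternating steps are
    scaled by the inverse left-right ratio; each sensor sees the shared
    source waveform attenuated by its distance to the moving footstep
    position. A leading pure-noise segment of ~2.5 s is included and its
    first 2 s marked as the noise reference.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _as_rng(rng_seed)
    fs = layout.sampling_rate

    mean_dt = profile.mean_step_time
    intervals = rng.normal(mean_dt, profile.step_time_jitter_sd, size=max(n_steps - 1, 0))
    intervals = np.clip(intervals, 0.25 * mean_dt, None)
    strike_times = LEAD_NOISE_S + 0.3 + np.concatenate([[0.0], np.cumsum(intervals)])
    strike_times = strike_times[:n_steps]

    total_s = (strike_times[-1] + 1.0) if n_steps else LEAD_NOISE_S + 1.0
    n_samples = int(round(total_s * fs))

    contact_idx = rng.choice(3, size=n_steps, p=np.asarray(profile.contact_type_probs))
    contact_types = [CONTACT_TYPES[i] for i in contact_idx]
    side_gain = np.where(
        np.arange(n_steps) % 2 == 0, 1.0, 1.0 / profile.left_right_amplitude_ratio
    )
    peak_forces = profile.force_scale * side_gain

    x0 = min(layout.positions) - 0.5
    step_positions = x0 + step_length * np.arange(n_steps)

    pulses = [
        generate_footstep_pulse(contact_types[i], peak_forces[i], floor, fs, rng)
        for i in range(n_steps)
    ]

    recordings = []
    for sid, pos in enumerate(layout.positions):
        sig = np.zeros(n_samples)
        for i in range(n_steps):
            gain = float(floor.attenuation(step_positions[i] - pos))
            start = int(round(strike_times[i] * fs))
            stop = min(start + pulses[i].size, n_samples)
            sig[start:stop] += gain * pulses[i][: stop - start]
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=n_samples)
        recordings.append(
            SensorRecording(
                samples=sig,
                sampling_rate=fs,
                sensor_id=sid,
                noise_reference=(0, int(NOISE_REF_S * fs)),
                position=pos,
            )
        )

    annotations = GroundTruthAnnotations(
        strike_times=strike_times,
        contact_types=contact_types,
        peak_forces=peak_forces,
        stage_label=stage_label,
        biometrics=biometrics,
    )
    return WalkTrace(recordings=recordings, annotations=annotations)


DISTRACTOR_KINDS = ("isolated_impulse", "long_transient", "short_blip")


def _distractor_waveform(kind: str, fs: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if kind == "isolated_impulse":
        # footstep-like 0.35 s transient (door slam / dropped item), but
        # with no neighbours -> fails the >= 3 consecutive-impulses rule
        t = np.arange(int(0.35 * fs)) / fs
        w = (1.0 - np.exp(-t / 0.008)) * np.exp(-((t / 0.12) ** 2)) * np.sin(2 * np.pi * 25.0 * t)
    elif kind == "long_transient":
        # 1.0 s rumble -> fails the 0.2-0.6 s duration rule
        n = int(1.0 * fs)
        t = np.arange(n) / fs
        w = np.hanning(n) * np.sin(2 * np.pi * 18.0 * t)
    elif kind == "short_blip":
        # 0.06 s click -> below the minimum footstep duration
        n = max(int(0.06 * fs), 4)
        t = np.arange(n) / fs
        w = np.hanning(n) * np.sin(2 * np.pi * 80.0 * t + rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown distractor kind {kind!r}")
    return amplitude * w


def inject_distractors(
    recording: SensorRecording,
    kinds: list[str],
    rng_seed: int | np.random.Generator | None = None,
) -> SensorRecording:
    """Superimpose non-footstep transients in a quiet tail of the recording.

    Distractors are appended after the walking activity, each separated by
    3 s (beyond the consecutiveness gap), and their intervals are logged in
    ``distractor_intervals`` so detection filters can be scored. The input
    recording is not modified.
    """
    rng = _as_rng(rng_seed)
    if not kinds:
        return recording
    for k in kinds:
        if k not in DISTRACTOR_KINDS:
            raise ValueError(f"unknown distractor kind {k!r}")
    fs = recording.sampling_rate
    a, b = recording.noise_reference if recording.noise_reference else (0, 0)
    noise_sd = float(np.std(recording.samples[a:b])) if b > a else 0.0
    amplitude = max(float(np.max(np.abs(recording.samples))), 1.0)

    gap = 3.0
    tail_needed = 1.5 + gap * len(kinds) + 1.5
    old_n = recording.samples.size
    n_extra = int(tail_needed * fs)
    tail = rng.normal(0.0, noise_sd, size=n_extra) if noise_sd > 0 else np.zeros(n_extra)
    samples = np.concatenate([recording.samples, tail])

    intervals = list(recording.distractor_intervals)
    t_cursor = old_n / fs + 1.5
    for kind in kinds:
        w = _distractor_waveform(kind, fs, amplitude, rng)
        start = int(round(t_cursor * fs))
        samples[start : start + w.size] += w
        intervals.append((start / fs, (start + w.size) / fs, kind))
        t_cursor += gap

    return SensorRecording(
        samples=samples,
        sampling_rate=fs,
        sensor_id=recording.sensor_id,
        noise_reference=recording.noise_reference,
        position=recording.position,
        distractor_intervals=intervals,
    )


def _biometrics_for_stage(rng: np.random.Generator) -> Biometrics:
    age = float(rng.uniform(7.0, 15.0))
    height = float(1.05 + 0.045 * (age - 7.0) + rng.normal(0.0, 0.04))
    bmi = float(rng.uniform(15.0, 22.0))
    weight = bmi * height**2
    gender = "male" if rng.random() < 0.5 else "female"
    return Biometrics(age=age, weight=weight, height=height, gender=gender)


def _run_time_for_stage(stage: int, bio: Biometrics, rng: np.random.Generator) -> float:
    """Invert the normative 100-m model so the run time reproduces the stage."""
    lo = STAGE_LOWER_BOUNDS[stage]
    hi = 115.0 if stage == 0 else STAGE_LOWER_BOUNDS[stage - 1]
    percent = float(rng.uniform(lo + 2.0, hi - 2.0))
    numerator = 36.72 - 1.51 * bio.age + 0.26 * bio.bmi
    return numerator / percent * 100.0


def generate_cohort(
    n_subjects: int,
    stage_distribution: np.ndarray | list[float],
    traces_per_subject_range: tuple[int, int] = (5, 10),
    rng_seed: int | np.random.Generator | None = None,
    layout: SensorLayout | None = None,
    floor: FloorModel | None = None,
    noise_sd: float = 0.02,
    n_steps_range: tuple[int, int] = (8, 12),
) -> list[SubjectData]:
    """Simulate a labeled cohort of subjects with stage-consistent biometrics.

    Each subject's 100-m run time is drawn by inverting the normative
    performance model, so applying the functional scale to the simulated
    biometrics and run time recovers the assigned stage exactly. Trace
    counts vary within ``traces_per_subject_range`` to exercise the
    rebalancing step.
    """
    p = np.asarray(stage_distribution, dtype=float)
    if p.size != 6 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("stage_distribution must be a simplex over stages 0-5")
    rng = _as_rng(rng_seed)
    layout = layout or SensorLayout()
    floor = floor or FloorModel()
    lo, hi = traces_per_subject_range

    cohort = []
    for sid in range(n_subjects):
        stage = int(rng.choice(6, p=p))
        bio = _biometrics_for_stage(rng)
        run_time = _run_time_for_stage(stage, bio, rng)
        n_traces = int(rng.integers(lo, hi + 1))
        traces = []
        for _ in range(n_traces):
            profile = gait_profile_for_stage(stage, rng)
            n_steps = int(rng.integers(n_steps_range[0], n_steps_range[1] + 1))
            traces.append(
                generate_walk_trace(
                    profile, n_steps, layout, floor, noise_sd, rng,
                    stage_label=stage, biometrics=bio,
                )
            )
        cohort.append(
            SubjectData(
                subject_id=sid,
                biometrics=bio,
                run_time_100m=run_time,
                stage=stage,
                traces=traces,
            )
        )
    return cohort
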