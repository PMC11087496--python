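"""Unified functional scale for muscular dystrophy based on 100-m run time.

The normative 100-m performance expresses a subject's actual run time
relative to an age/BMI-normed reference speed:

    predicted 100m % = (36.72 - 1.51*age + 0.26*weight/height^2)
                       / actual_time * 100

where age is in years, weight in kg and height in m. 100% means the
subject runs at the median speed of age-matched healthy controls. The
percentage is discretized into functional stages 0-7; ambulatory stages
0-5 are the prediction targets of the vibration-sensing system.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import Biometrics

__all__ = [
    "FunctionalStage",
    "predicted_100m_percent",
    "stage_from_percent",
    "stage_for_subject",
    "STAGE_LOWER_BOUNDS",
]

# Lower percent edge per stage; intervals are half-open [lo, next_lo).
# Stage 0 is percent >= 100 (faster than the 50th-percentile control).
STAGE_LOWER_BOUNDS: dict[int, float] = {
    0: 100.0,
    1: 80.0,
    2: 60.0,
    3: 50.0,
    4: 40.0,
    5: 30.0,
    6: 20.0,
    7: 0.0,
}


@dataclass(frozen=True)
class FunctionalStage:
    stage: int
    predicted_100m_percent: float


def predicted_100m_percent(bio: Biometrics, actual_100m_time: float) -> float:
    """Normative 100-m performance (%) from biometrics and actual run time.

    Raises ``ValueError`` for a non-positive run time or a non-positive
    normative numerator (outside the model's calibration range).
    """
    if actual_100m_time <= 0:
        raise ValueError("actual_100m_time must be positive")
    numerator = 36.72 - 1.51 * bio.age + 0.26 * bio.weight / bio.height**2
    if numerator <= 0:
        raise ValueError(
            "normative speed model is non-positive for these biometrics "
            f"(age={bio.age}, bmi={bio.bmi:.1f})"
        )
    return numerator / actual_100m_time * 100.0


def stage_from_percent(percent: float) -> int:
    """Map a predicted 100m % to the functional stage 0-7 (monotone, total)."""
    if percent < 0:
        raise ValueError("percent must be non-negative")
    for stage in range(8):
        if percent >= STAGE_LOWER_BOUNDS[stage]:
            return stage
    return 7  # unreachable: stage 7 lower bound is 0


def stage_for_subject(bio: Biometrics, actual_100m_time: float) -> FunctionalStage:
    """Convenience: percent and stage in one call."""
    pct = predicted_100m_percent(bio, actual_100m_time)
    return FunctionalStage(stage=stage_from_percent(pct), predicted_100m_percent=pct)
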