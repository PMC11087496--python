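"""Implicit signal-based features of footstep vibration.

Per footstep: time-domain moments (mean, sd, skewness, kurtosis),
dominant frequencies of the strike and push-off phases, a unit-sum PSD
summary, energy and a clipping flag. Per trace: energy variability
(coefficient of variation of footstep energies) and the representative
footstep, i.e. the unclipped footstep of highest energy.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps, stats

from .records import FootstepImpulse
from .symptoms import SPECTRUM_MAX_HZ

__all__ = [
    "basic_stats",
    "dominant_frequency",
    "footstep_energy",
    "energy_variability",
    "is_clipped",
    "representative_footstep",
    "psd_band_powers",
]

PHASE_FRACTION = 0.4  # strike = first 40% of the window, off = last 40%


def basic_stats(impulse: FootstepImpulse) -> tuple[float, float, float, float]:
    """Sample mean, sd (n-1), skewness and kurtosis (Normal -> 3).

    A constant signal has sd 0 and, by convention, skewness and kurtosis 0.
    """
    x = impulse.samples
    if x.size < 4:
        raise ValueError("basic stats require at least 4 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return float(x[0]), 0.0, 0.0, 0.0
    return (
        float(np.mean(x)),
        sd,
        float(stats.skew(x)),
        float(stats.kurtosis(x, fisher=False)),
    )


def dominant_frequency(impulse: FootstepImpulse, phase: str = "strike") -> float:
    """Frequency (Hz) of maximal power in the strike or push-off phase.

    The strike phase is the first 40% of the impulse window, the off
    phase the last 40%; the search is band-limited to 0-250 Hz. A
    DC-only segment yields 0 Hz.
    """
    if phase not in ("strike", "off"):
        raise ValueError("phase must be 'strike' or 'off'")
    x = impulse.samples
    n_seg = max(int(round(PHASE_FRACTION * x.size)), 4)
    seg = x[:n_seg] if phase == "strike" else x[-n_seg:]
    freqs, pxx = sps.periodogram(seg, fs=impulse.sampling_rate)
    mask = freqs <= min(SPECTRUM_MAX_HZ, impulse.sampling_rate / 2)
    freqs, pxx = freqs[mask], pxx[mask]
    return float(freqs[int(np.argmax(pxx))])


def footstep_energy(impulse: FootstepImpulse) -> float:
    """Signal energy: sum of squared samples (proxy for footstep force)."""
    return float(np.sum(impulse.samples**2))


def energy_variability(energies: np.ndarray) -> float:
    """Coefficient of variation (population sd / mean) of footstep energies."""
    energies = np.asarray(energies, dtype=float)
    if energies.size < 2:
        raise ValueError("energy variability requires at least 2 footsteps")
    mean = float(np.mean(energies))
    if mean == 0:
        raise ValueError("energy variability undefined for zero mean energy")
    return float(np.std(energies) / mean)


def is_clipped(impulse: FootstepImpulse, full_scale: float) -> bool:
    """True iff at least 3 consecutive samples sit at >= 99% of full scale."""
    if full_scale <= 0:
        raise ValueError("full_scale must be positive")
    at_rail = np.abs(impulse.samples) >= 0.99 * full_scale
    run = 0
    for flag in at_rail:
        run = run + 1 if flag else 0
        if run >= 3:
            return True
    return False


def representative_footstep(footsteps: list[FootstepImpulse]) -> FootstepImpulse:
    """The unclipped footstep of maximal energy.

    If every footstep is clipped, the one with the fewest at-rail samples
    (smallest clipping extent) is returned, ties broken by energy.
    """
    if not footsteps:
        raise ValueError("trace has no footsteps")
    unclipped = [f for f in footsteps if not f.clipped]
    if unclipped:
        return max(unclipped, key=footstep_energy)
    scale = max(float(np.max(np.abs(f.samples))) for f in footsteps)

    def clip_extent(f: FootstepImpulse) -> int:
        return int(np.sum(np.abs(f.samples) >= 0.99 * scale))

    return min(footsteps, key=lambda f: (clip_extent(f), -footstep_energy(f)))


def psd_band_powers(
    impulse: FootstepImpulse, n_bands: int = 8, f_lo: float = 1.0, f_hi: float = SPECTRUM_MAX_HZ
) -> np.ndarray:
    """Unit-sum power in log-spaced frequency bands over [f_lo, f_hi] Hz."""
    freqs, pxx = sps.periodogram(impulse.samples, fs=impulse.sampling_rate, window="hann")
    f_hi = min(f_hi, impulse.sampling_rate / 2)
    edges = np.geomspace(f_lo, f_hi, n_bands + 1)
    powers = np.zeros(n_bands)
    for k in range(n_bands):
        mask = (freqs >= edges[k]) & (freqs < edges[k + 1])
        powers[k] = pxx[mask].sum()
    total = powers.sum()
    if total == 0:
        return np.full(n_bands, 1.0 / n_bands)
    return powers / total
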