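"""Footstep-impulse detection, filtering and denoising for floor vibration.

The detector compares 0.1-s sliding windows of the streaming signal with
a pure-noise reference: windows whose rectified mean amplitude exceeds
the noise mean by more than three noise standard deviations become
impulse candidates. Candidates are then filtered by the two footstep
signatures: a typical duration of 0.2-0.6 s, and at least three
consecutive impulses as the walker passes (door slams and dropped items
produce isolated transients). Denoising is a lowpass filter (gait
content sits below 250 Hz) followed by spectral-subtraction Wiener
gains estimated from the noise reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import FootstepImpulse, SensorRecording

__all__ = [
    "NoiseStats",
    "estimate_noise_stats",
    "detect_impulses",
    "filter_footstep_impulses",
    "lowpass_filter",
    "wiener_denoise",
    "segment_footsteps",
    "rebalance_subjects",
    "DURATION_RANGE_S",
    "GAP_MAX_S",
    "MIN_CONSECUTIVE",
]

WINDOW_S = 0.1  # detection window length
DURATION_RANGE_S = (0.2, 0.6)  # admissible footstep-impulse duration
MIN_CONSECUTIVE = 3  # impulses per run required for footstep origin
GAP_MAX_S = 2.0  # inter-onset gap defining "consecutive" impulses
ABS_FLOOR = 1e-6  # absolute threshold when the noise reference is silent


@dataclass(frozen=True)
class NoiseStats:
    """Ambient-noise statistics estimated from a pure-noise reference."""

    mean: float
    sd: float
    freqs: np.ndarray  # Hz
    spectrum: np.ndarray  # power spectral density, V^2/Hz

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if np.any(self.spectrum < 0):
            raise ValueError("spectrum must be non-negative")


def estimate_noise_stats(recording: SensorRecording) -> NoiseStats:
    """Mean, sd and periodogram of the recording's noise-reference segment.

    Requires a reference of at least 1 s.
    """
    if recording.noise_reference is None:
        raise ValueError("recording has no noise-reference interval")
    a, b = recording.noise_reference
    if (b - a) < recording.sampling_rate:
        raise ValueError("noise reference must be at least 1 s long")
    ref = recording.samples[a:b]
    freqs, pxx = sps.periodogram(ref, fs=recording.sampling_rate)
    return NoiseStats(mean=float(np.mean(ref)), sd=float(np.std(ref)), freqs=freqs, spectrum=pxx)


def detect_impulses(
    recording: SensorRecording, noise: NoiseStats
) -> list[tuple[float, float]]:
    """Find candidate impulse intervals as runs of super-threshold windows.

    The statistic per 0.1-s sliding window (half-window hop) is the mean
    absolute amplitude; the threshold is ``noise.mean + 3 * noise.sd``
    (an absolute floor replaces a degenerate zero-noise threshold).
    Overlapping super-threshold windows merge into one candidate spanning
    their union. Returns half-open ``(onset_s, offset_s)`` intervals
    sorted by onset.
    """
    fs = recording.sampling_rate
    win = int(round(WINDOW_S * fs))
    hop = max(win // 2, 1)
    x = recording.samples
    if x.size <= win:
        raise ValueError("recording must be longer than one 0.1-s window")
    n_win = (x.size - win) // hop + 1
    starts = np.arange(n_win) * hop
    csum = np.concatenate([[0.0], np.cumsum(np.abs(x))])
    stats = (csum[starts + win] - csum[starts]) / win
    threshold = noise.mean + 3.0 * noise.sd
    if noise.sd == 0:
        threshold = max(threshold, ABS_FLOOR)
    above = stats > threshold

    intervals: list[tuple[float, float]] = []
    i = 0
    while i < n_win:
        if above[i]:
            j = i
            while j + 1 < n_win and above[j + 1]:
                j += 1
            intervals.append((starts[i] / fs, (starts[j] + win) / fs))
            i = j + 1
        else:
            i += 1
    return intervals


def filter_footstep_impulses(
    candidates: list[tuple[float, float]],
    duration_range: tuple[float, float] = DURATION_RANGE_S,
    gap_max: float = GAP_MAX_S,
    min_consecutive: int = MIN_CONSECUTIVE,
) -> list[tuple[float, float]]:
    """Keep only footstep-like candidates.

    First drops candidates whose duration lies outside ``duration_range``,
    then drops runs of fewer than ``min_consecutive`` candidates, where
    candidates are consecutive when their inter-onset gap is at most
    ``gap_max``. Idempotent.
    """
    lo, hi = duration_range
    eps = 1e-9  # duration bounds are inclusive despite float round-off
    kept = [(a, b) for a, b in candidates if lo - eps <= (b - a) <= hi + eps]
    if not kept:
        return []
    onsets = np.array([a for a, _ in kept])
    if np.any(np.diff(onsets) < 0):
        raise ValueError("candidates must be sorted by onset")

    accepted: list[tuple[float, float]] = []
    run: list[tuple[float, float]] = [kept[0]]
    for cand in kept[1:]:
        if cand[0] - run[-1][0] <= gap_max:
            run.append(cand)
        else:
            if len(run) >= min_consecutive:
                accepted.extend(run)
            run = [cand]
    if len(run) >= min_consecutive:
        accepted.extend(run)
    return accepted


def lowpass_filter(recording: SensorRecording, cutoff: float = 500.0) -> SensorRecording:
    """Zero-phase Butterworth lowpass (order 8, forward-backward).

    Identity when the sampling rate is at most twice the cutoff (the
    lab's 500 Hz data already carries nothing above the cutoff). The
    zero-phase form avoids biasing onset times that feed step-time
    estimation.
    """
    if recording.sampling_rate <= 2.0 * cutoff:
        return recording
    sos = sps.butter(8, cutoff, btype="low", fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples)
    return SensorRecording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        sensor_id=recording.sensor_id,
        noise_reference=recording.noise_reference,
        position=recording.position,
        distractor_intervals=list(recording.distractor_intervals),
    )


def wiener_denoise(recording: SensorRecording, noise: NoiseStats) -> SensorRecording:
    """Spectral-subtraction Wiener filter using the noise-reference PSD.

    Per frequency bin the gain is ``S_hat / (S_hat + N)`` with
    ``S_hat = max(|X|^2 - N, 0)`` (signal power estimated by subtracting
    the noise spectrum), so gains lie in [0, 1] and output power never
    exceeds input power in any bin.
    """
    x = recording.samples
    n = x.size
    fs = recording.sampling_rate
    xf = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # noise periodogram (V^2/Hz) -> expected |X|^2 on this FFT grid
    noise_power = np.interp(freqs, noise.freqs, noise.spectrum) * fs * n / 2.0
    power = np.abs(xf) ** 2
    s_hat = np.maximum(power - noise_power, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(s_hat + noise_power > 0, s_hat / (s_hat + noise_power), 1.0)
    gain = np.clip(gain, 0.0, 1.0)
    cleaned = np.fft.irfft(xf * gain, n=n)
    return SensorRecording(
        samples=cleaned,
        sampling_rate=fs,
        sensor_id=recording.sensor_id,
        noise_reference=recording.noise_reference,
        position=recording.position,
        distractor_intervals=list(recording.distractor_intervals),
    )


def segment_footsteps(
    recording: SensorRecording,
    accepted: list[tuple[float, float]],
    full_scale: float | None = None,
) -> list[FootstepImpulse]:
    """Extract per-impulse sample windows as :class:`FootstepImpulse` objects.

    ``full_scale`` (volts) enables the clipping flag; when omitted no
    impulse is marked clipped.
    """
    from .sigfeat import is_clipped  # local import to avoid a cycle

    fs = recording.sampling_rate
    impulses = []
    for k, (a, b) in enumerate(accepted, start=1):
        ia, ib = int(round(a * fs)), int(round(b * fs))
        if ia < 0 or ib > recording.samples.size or ia >= ib:
            raise ValueError(f"interval ({a}, {b}) out of recording bounds")
        imp = FootstepImpulse(
            onset_time=a,
            offset_time=b,
            samples=recording.samples[ia:ib].copy(),
            sampling_rate=fs,
            sensor_id=recording.sensor_id,
            index_in_trace=k,
        )
        if full_scale is not None:
            imp.clipped = is_clipped(imp, full_scale)
        impulses.append(imp)
    return impulses


def rebalance_subjects(
    per_subject_samples: dict | list,
    rng_seed: int | np.random.Generator | None = None,
) -> dict | list:
    """Equalize per-subject sample counts at the cohort median.

    Subjects below the median count are bootstrapped (sampled with
    replacement), subjects above are down-sampled without replacement;
    subjects at the median are left untouched. The median uses the
    interpolated (midpoint) convention rounded to the nearest integer.
    """
    items = (
        list(per_subject_samples.items())
        if isinstance(per_subject_samples, dict)
        else list(enumerate(per_subject_samples))
    )
    if not items:
        raise ValueError("at least one subject required")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    counts = [len(v) for _, v in items]
    target = int(round(float(np.median(counts))))

    out = {}
    for key, samples in items:
        n = len(samples)
        if n == target:
            out[key] = list(samples)
        elif n < target:
            idx = rng.integers(0, n, size=target)
            out[key] = [samples[i] for i in idx]
        else:
            idx = rng.choice(n, size=target, replace=False)
            out[key] = [samples[i] for i in sorted(idx)]
    if isinstance(per_subject_samples, dict):
        return out
    return [out[i] for i in range(len(items))]
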