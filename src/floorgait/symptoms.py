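"""Symptom-based gait features from footstep-induced floor vibration.

Foot-strike times are located by a continuous wavelet transform with a
generalized Morse wavelet restricted to the floor's natural-frequency
band (5-25 Hz): each strike excites the floor resonance, so the summed
coefficient magnitude over that band peaks once per footstep. From the
strike sequence follow the temporal symptoms:

    step time_i = t_strike^(i+1) - t_strike^(i)
    cadence     = (N - 1) / (t_strike^N - t_strike^1)      [per minute]
    variability = sample sd of the step times

Left-right symmetry compares adjacent footsteps' 90th-percentile
amplitudes X90 (the 90th percentile is robust to clipping and noise
spikes):

    symmetry = 1 - (1/(N-1)) * sum |X90^(i+1) - X90^(i)|
                               / (0.5 * (X90^(i+1) + X90^(i)))

which is 1 for perfectly alternating-equal steps and falls (possibly
below 0) with asymmetry. Initial-contact type (heel/midfoot/toe) is
classified from the normalized footstep spectrum with a quadratic-kernel
support vector machine whose margins are calibrated to probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import signal as sps
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .records import FootstepImpulse, SensorRecording

__all__ = [
    "StrikeSequence",
    "ContactModel",
    "morse_filter_bank",
    "wavelet_band_envelope",
    "detect_foot_strikes",
    "strikes_from_recording",
    "step_times",
    "cadence",
    "step_time_variability",
    "x90_amplitude",
    "symmetry_score",
    "footstep_spectrum",
    "train_contact_classifier",
    "toe_contact_probability",
]

FLOOR_BAND_HZ = (5.0, 25.0)
MORSE_GAMMA = 3.0  # symmetric family member
MORSE_BETA = 3.0  # time-bandwidth resolving 5-25 Hz at ~0.05 s precision
SPECTRUM_MAX_HZ = 250.0


@dataclass(frozen=True)
class StrikeSequence:
    """Strictly increasing foot-strike times (s) of one trace."""

    strike_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "strike_times", np.asarray(self.strike_times, dtype=float)
        )
        if self.strike_times.size and np.any(np.diff(self.strike_times) <= 0):
            raise ValueError("strike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.strike_times.size)


def morse_filter_bank(
    n_samples: int,
    sampling_rate: float,
    band: tuple[float, float] = FLOOR_BAND_HZ,
    n_freqs: int = 12,
    beta: float = MORSE_BETA,
    gamma: float = MORSE_GAMMA,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Morse-wavelet filters on the FFT grid.

    The generalized Morse wavelet has the frequency-domain form
    ``a(w) = (w/wp)^beta * exp((beta/gamma) * (1 - (w/wp)^gamma))`` for
    w > 0 (zero otherwise), peak-normalized at the center frequency wp.
    Returns ``(center_freqs, filters)`` with one row per log-spaced
    center frequency in ``band``.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= sampling_rate / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    centers = np.geomspace(lo, hi, n_freqs)
    freqs = np.fft.fftfreq(n_samples, d=1.0 / sampling_rate)
    pos = freqs > 0
    filters = np.zeros((n_freqs, n_samples))
    for k, fc in enumerate(centers):
        ratio = freqs[pos] / fc
        filters[k, pos] = ratio**beta * np.exp((beta / gamma) * (1.0 - ratio**gamma))
    return centers, filters


def wavelet_band_envelope(
    recording: SensorRecording,
    band: tuple[float, float] = FLOOR_BAND_HZ,
    n_freqs: int = 12,
) -> np.ndarray:
    """Summed Morse-CWT coefficient magnitude over the floor band.

    Non-negative everywhere; peaks once per footstep at the strike-driven
    resonance burst.
    """
    x = recording.samples
    _, filters = morse_filter_bank(x.size, recording.sampling_rate, band, n_freqs)
    xf = np.fft.fft(x)
    coeffs = np.fft.ifft(xf[None, :] * filters, axis=1)
    return np.abs(coeffs).sum(axis=0)


def detect_foot_strikes(
    envelope: np.ndarray,
    sampling_rate: float,
    min_separation: float = 0.25,
    prominence_factor: float = 3.0,
) -> StrikeSequence:
    """Peak-pick the band envelope into a strike sequence.

    Keeps local maxima with prominence at least ``prominence_factor``
    times the median envelope and pairwise separation at least
    ``min_separation`` seconds (the larger peak wins within a
    separation window). Each peak is then walked back to its rising edge
    (where the envelope last crossed ``onset_fraction`` of the peak
    height), since the strike happens at the start of the impulse, not
    at its energy maximum. A flat envelope yields an empty sequence.
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    if envelope.size == 0 or envelope.max() == 0:
        return StrikeSequence(np.empty(0))
    prominence = prominence_factor * float(np.median(envelope))
    prominence = max(prominence, 1e-12 * envelope.max())
    distance = max(int(round(min_separation * sampling_rate)), 1)
    peaks, _ = sps.find_peaks(envelope, prominence=prominence, distance=distance)

    onset_fraction = 0.25
    max_back = distance
    onsets = []
    for p in peaks:
        thr = onset_fraction * envelope[p]
        j = p
        while j > 0 and (p - j) < max_back and envelope[j - 1] > thr:
            j -= 1
        onsets.append(j)
    onsets = np.asarray(onsets, dtype=float)
    onsets += np.arange(onsets.size) * 1e-9  # guard exact ties
    return StrikeSequence(onsets / sampling_rate)


def strikes_from_recording(
    recording: SensorRecording,
    band: tuple[float, float] = FLOOR_BAND_HZ,
    min_separation: float = 0.25,
    prominence_factor: float = 3.0,
) -> StrikeSequence:
    """Convenience: band envelope followed by peak-picking."""
    env = wavelet_band_envelope(recording, band)
    return detect_foot_strikes(env, recording.sampling_rate, min_separation, prominence_factor)


def step_times(strikes: StrikeSequence) -> np.ndarray:
    """Successive inter-strike intervals (s); empty when fewer than 2 strikes."""
    if strikes.n < 2:
        return np.empty(0)
    return np.diff(strikes.strike_times)


def cadence(strikes: StrikeSequence) -> float:
    """Steps per minute: (N-1) strikes-per-second over the trace span, x60."""
    if strikes.n < 2:
        raise ValueError("cadence requires at least 2 strikes")
    t = strikes.strike_times
    span = t[-1] - t[0]
    return (strikes.n - 1) / span * 60.0


def step_time_variability(times: np.ndarray) -> float:
    """Sample (n-1) standard deviation of the step times."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("variability requires at least 2 step times")
    return float(np.std(times, ddof=1))


def x90_amplitude(impulse: FootstepImpulse) -> float:
    """90th percentile of the absolute sample amplitude of one footstep."""
    return float(np.percentile(np.abs(impulse.samples), 90))


def symmetry_score(x90: np.ndarray) -> float:
    """Left-right symmetry from adjacent footsteps' X90 amplitudes.

    1 when all adjacent pairs match; decreases (unclamped, can go
    negative) with asymmetry. Requires N >= 2 and positive amplitudes.
    """
    x90 = np.asarray(x90, dtype=float)
    if x90.size < 2:
        raise ValueError("symmetry score requires at least 2 footsteps")
    if np.any(x90 <= 0):
        raise ValueError("all X90 amplitudes must be positive")
    num = np.abs(np.diff(x90))
    den = 0.5 * (x90[1:] + x90[:-1])
    return float(1.0 - np.mean(num / den))


def footstep_spectrum(impulse: FootstepImpulse, n_bins: int = 25) -> np.ndarray:
    """Unit-sum power spectrum of one footstep over 0-250 Hz in n_bins bands.

    Hann-windowed periodogram, band-limited to 0-250 Hz, power averaged
    into equal-width bins and normalized to total 1 (scale-invariant).
    """
    if impulse.samples.size == 0:
        raise ValueError("impulse is empty")
    freqs, pxx = sps.periodogram(impulse.samples, fs=impulse.sampling_rate, window="hann")
    top = min(SPECTRUM_MAX_HZ, impulse.sampling_rate / 2)
    edges = np.linspace(0.0, top, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, n_bins - 1)
    mask = freqs <= top
    binned = np.bincount(idx[mask], weights=pxx[mask], minlength=n_bins)
    total = binned.sum()
    if total == 0:
        return np.full(n_bins, 1.0 / n_bins)
    return binned / total


@dataclass
class ContactModel:
    """Quadratic-kernel margin classifier over normalized footstep spectra.

    Margins are calibrated to class probabilities by cross-validated
    sigmoid (Platt) fitting; the three class probabilities form a
    simplex.
    """

    svc: CalibratedClassifierCV
    classes: tuple[str, ...]
    n_bins: int
    version: str = "1"

    def predict_proba(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.atleast_2d(spectra)
        return self.svc.predict_proba(spectra)

    def save(self, path) -> None:
        joblib.dump(
            {"version": self.version, "classes": self.classes,
             "n_bins": self.n_bins, "svc": self.svc},
            path,
        )

    @classmethod
    def load(cls, path) -> "ContactModel":
        blob = joblib.load(path)
        return cls(svc=blob["svc"], classes=tuple(blob["classes"]),
                   n_bins=blob["n_bins"], version=blob["version"])


def train_contact_classifier(
    spectra: np.ndarray,
    labels: list[str],
    rng_seed: int = 0,
) -> ContactModel:
    """Fit the initial-contact classifier on labeled footstep spectra.

    Requires at least 2 classes and 5 examples per class. The degree-2
    polynomial kernel captures interactions between frequency bands.
    """
    spectra = np.asarray(spectra, dtype=float)
    labels = list(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 examples")
    base = SVC(kernel="poly", degree=2, C=10.0, random_state=rng_seed)
    clf = CalibratedClassifierCV(base, method="sigmoid", ensemble=False)
    clf.fit(spectra, labels)
    return ContactModel(svc=clf, classes=tuple(clf.classes_), n_bins=spectra.shape[1])


def toe_contact_probability(model: ContactModel, spectrum: np.ndarray) -> float:
    """Calibrated probability that the footstep is a toe contact."""
    if "toe" not in model.classes:
        raise ValueError("model was not trained with a 'toe' class")
    proba = model.predict_proba(spectrum)[0]
    return float(proba[model.classes.index("toe")])
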