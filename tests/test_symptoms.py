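"""Symptom features: wavelet strikes, temporal symptoms, symmetry, contacts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from floorgait import symptoms
from floorgait.records import FootstepImpulse, SensorRecording
from floorgait.symptoms import (
    StrikeSequence,
    cadence,
    detect_foot_strikes,
    footstep_spectrum,
    step_time_variability,
    step_times,
    symmetry_score,
    toe_contact_probability,
    wavelet_band_envelope,
    x90_amplitude,
)
from floorgait.synthetic import gait_profile_for_stage, generate_walk_trace


def _rec(samples, fs=500.0):
    return SensorRecording(samples=np.asarray(samples, float), sampling_rate=fs)


class TestBandEnvelope:
    def test_zero_signal_zero_envelope(self):
        env = wavelet_band_envelope(_rec(np.zeros(1000)))
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_band_isolation(self):
        t = np.arange(2000) / 500.0
        env_in = wavelet_band_envelope(_rec(np.sin(2 * np.pi * 15 * t)))
        env_out = wavelet_band_envelope(_rec(np.sin(2 * np.pi * 100 * t)))
        assert env_in.mean() >= 5 * env_out.mean()

    def test_envelope_peaks_at_strikes(self, layout, floor):
        trace = generate_walk_trace(
            gait_profile_for_stage(0, 4), 6, layout, floor, 0.0, 4
        )
        rec = trace.recordings[1]
        env = wavelet_band_envelope(rec)
        strikes = detect_foot_strikes(env, rec.sampling_rate)
        assert strikes.n == 6
        err = np.abs(strikes.strike_times - trace.annotations.strike_times)
        assert np.all(err <= 0.05)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            wavelet_band_envelope(_rec(np.zeros(100)), band=(25.0, 5.0))


class TestPeakPicking:
    def test_flat_envelope_no_strikes(self):
        assert detect_foot_strikes(np.zeros(1000), 500.0).n == 0

    def test_close_peaks_resolve_to_larger(self):
        env = np.zeros(1000)
        env[400] = 1.0
        env[450] = 2.0  # 0.1 s later
        strikes = detect_foot_strikes(env, 500.0, min_separation=0.25)
        assert strikes.n == 1
        assert strikes.strike_times[0] == pytest.approx(0.9)

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            detect_foot_strikes(np.array([-1.0, 0.0]), 500.0)


class TestTemporalSymptoms:
    def test_step_times_from_strikes(self):
        st_ = step_times(StrikeSequence(np.array([0.0, 0.5, 1.1])))
        np.testing.assert_allclose(st_, [0.5, 0.6])

    def test_single_strike_empty(self):
        assert step_times(StrikeSequence(np.array([1.0]))).size == 0

    def test_cadence_arithmetic(self):
        strikes = StrikeSequence(np.arange(10) * 0.5)
        assert cadence(strikes) == pytest.approx(120.0)
        assert cadence(StrikeSequence(np.array([0.0, 1.0]))) == pytest.approx(60.0)

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_cadence_translation_invariant(self, shift):
        base = np.array([0.0, 0.6, 1.1, 1.7])
        assert cadence(StrikeSequence(base + shift)) == pytest.approx(
            cadence(StrikeSequence(base))
        )

    def test_cadence_requires_two_strikes(self):
        with pytest.raises(ValueError):
            cadence(StrikeSequence(np.array([1.0])))

    def test_variability_closed_form(self):
        assert step_time_variability([0.4, 0.6]) == pytest.approx(np.sqrt(0.02))
        assert step_time_variability([0.5, 0.5, 0.5]) == 0.0
        assert step_time_variability([0.8, 1.2]) == pytest.approx(
            2 * step_time_variability([0.4, 0.6])
        )


class TestSymmetryScore:
    def test_equal_amplitudes_fully_symmetric(self):
        assert symmetry_score([2.0, 2.0, 2.0]) == pytest.approx(1.0)

    def test_worked_examples(self):
        assert symmetry_score([1.0, 3.0]) == pytest.approx(0.0)
        assert symmetry_score([2.0, 2.0, 4.0]) == pytest.approx(1 - np.mean([0, 2 / 3]))

    @given(
        st.lists(st.floats(min_value=0.1, max_value=50), min_size=2, max_size=10),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariance(self, x90, c):
        x = np.asarray(x90)
        assert symmetry_score(c * x) == pytest.approx(symmetry_score(x), abs=1e-9)

    @given(st.floats(min_value=0.1, max_value=50), st.floats(min_value=0.1, max_value=50))
    def test_pair_reversal_invariance(self, a, b):
        assert symmetry_score([a, b]) == pytest.approx(symmetry_score([b, a]))

    def test_zero_amplitude_signaled(self):
        with pytest.raises(ValueError):
            symmetry_score([0.0, 1.0])

    def test_decreases_with_simulated_asymmetry(self, layout, floor):
        """Expected symmetry falls as the left-right force ratio departs from 1."""
        from floorgait.evaluation import process_recording

        means = []
        for ratio in (1.0, 1.4, 1.9):
            scores = []
            rng = np.random.default_rng(30)
            for _ in range(12):
                profile = symptoms_profile(ratio, rng)
                trace = generate_walk_trace(profile, 10, layout, floor, 0.01, rng)
                for rec in trace.recordings:
                    impulses, _ = process_recording(rec)
                    if len(impulses) < 3:
                        continue
                    x90 = np.array([x90_amplitude(i) for i in impulses])
                    if np.all(x90 > 0):
                        scores.append(symmetry_score(x90))
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


def symptoms_profile(ratio, rng):
    from floorgait.synthetic import GaitProfile

    return GaitProfile(
        cadence=float(110 + rng.normal(0, 2)),
        step_time_jitter_sd=0.01,
        left_right_amplitude_ratio=ratio,
        contact_type_probs=(0.8, 0.15, 0.05),
    )


class TestFootstepSpectrum:
    def _impulse(self, freq, fs=500.0, dur=0.4):
        t = np.arange(int(dur * fs)) / fs
        return FootstepImpulse(0.0, dur, np.sin(2 * np.pi * freq * t), fs)

    def test_unit_sum(self):
        spec = footstep_spectrum(self._impulse(25.0), n_bins=25)
        assert spec.sum() == pytest.approx(1.0)

    def test_tone_concentrates_in_its_bin(self):
        # 25 Hz sits at the center of bin 2 for 10 Hz-wide bins
        spec = footstep_spectrum(self._impulse(25.0), n_bins=25)
        assert spec[2] > 0.8

    def test_amplitude_scale_invariance(self):
        imp = self._impulse(40.0)
        scaled = FootstepImpulse(0.0, imp.duration, 7.5 * imp.samples, 500.0)
        np.testing.assert_allclose(
            footstep_spectrum(imp), footstep_spectrum(scaled), atol=1e-12
        )


class TestContactClassifier:
    def test_probabilities_form_simplex(self, contact_model, floor):
        from floorgait.synthetic import generate_footstep_pulse

        pulse = generate_footstep_pulse("midfoot", 1.0, floor, 500.0, 0)
        imp = FootstepImpulse(0.0, pulse.size / 500.0, pulse, 500.0)
        proba = contact_model.predict_proba(footstep_spectrum(imp, 25))
        assert proba.shape == (1, 3)
        assert proba.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("contact,expect_toe", [("toe", True), ("heel", False)])
    def test_toe_probability_separates_contacts(self, contact_model, floor, contact, expect_toe):
        from floorgait.synthetic import generate_footstep_pulse

        pulse = generate_footstep_pulse(contact, 1.0, floor, 500.0, 5)
        imp = FootstepImpulse(0.0, pulse.size / 500.0, pulse, 500.0)
        p_toe = toe_contact_probability(contact_model, footstep_spectrum(imp, 25))
        assert (p_toe > 0.5) == expect_toe

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 25))
        with pytest.raises(ValueError):
            symptoms.train_contact_classifier(X, ["heel"] * 10)

    def test_underpopulated_class_rejected(self):
        X = np.random.default_rng(0).random((8, 25))
        with pytest.raises(ValueError):
            symptoms.train_contact_classifier(X, ["heel"] * 5 + ["toe"] * 3)

    def test_model_round_trips_through_file(self, contact_model, tmp_path):
        path = tmp_path / "contact_model.joblib"
        contact_model.save(path)
        loaded = symptoms.ContactModel.load(path)
        assert loaded.classes == contact_model.classes
        X = np.full((1, contact_model.n_bins), 1.0 / contact_model.n_bins)
        np.testing.assert_allclose(
            loaded.predict_proba(X), contact_model.predict_proba(X)
        )
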