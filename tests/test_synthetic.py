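"""Simulator contracts: pulses, stage profiles, traces, distractors, cohorts."""

import numpy as np
import pytest

from floorgait.records import FootstepImpulse
from floorgait.scale import stage_for_subject
from floorgait.sigfeat import dominant_frequency
from floorgait.synthetic import (
    FloorModel,
    GaitProfile,
    SensorLayout,
    gait_profile_for_stage,
    generate_cohort,
    generate_footstep_pulse,
    generate_walk_trace,
    inject_distractors,
)


def _domf(pulse, fs=500.0):
    imp = FootstepImpulse(0.0, pulse.size / fs, pulse, fs)
    return dominant_frequency(imp, "strike")


class TestFootstepPulse:
    def test_duration_within_footstep_range(self, floor):
        for seed in range(5):
            for contact in ("heel", "midfoot", "toe"):
                p = generate_footstep_pulse(contact, 1.0, floor, 500.0, seed)
                assert 0.2 <= p.size / 500.0 <= 0.6

    def test_contact_dominant_frequency_ordering(self, floor):
        heel = _domf(generate_footstep_pulse("heel", 1.0, floor, 500.0, 3))
        mid = _domf(generate_footstep_pulse("midfoot", 1.0, floor, 500.0, 3))
        toe = _domf(generate_footstep_pulse("toe", 1.0, floor, 500.0, 3))
        assert heel < mid < toe

    def test_zero_force_is_silence(self, floor):
        p = generate_footstep_pulse("heel", 0.0, floor, 500.0, 0)
        assert np.all(p == 0)

    def test_seed_determinism(self, floor):
        a = generate_footstep_pulse("toe", 1.2, floor, 500.0, 42)
        b = generate_footstep_pulse("toe", 1.2, floor, 500.0, 42)
        np.testing.assert_array_equal(a, b)

    def test_unknown_contact_rejected(self, floor):
        with pytest.raises(ValueError):
            generate_footstep_pulse("sideways", 1.0, floor, 500.0, 0)


class TestStageProfiles:
    def test_stage0_profile_is_healthy(self):
        p = gait_profile_for_stage(0, 1)
        assert p.contact_type_probs[2] < 0.1
        assert p.left_right_amplitude_ratio == 1.0

    def test_toe_probability_monotone_in_stage(self):
        toes = [gait_profile_for_stage(s, 5).contact_type_probs[2] for s in range(6)]
        assert all(b > a for a, b in zip(toes, toes[1:]))
        assert toes[5] > toes[1]

    def test_asymmetry_grows_with_stage(self):
        ratios = [gait_profile_for_stage(s, 9).left_right_amplitude_ratio for s in range(6)]
        departures = [abs(r - 1.0) for r in ratios]
        assert all(b > a for a, b in zip(departures, departures[1:]))

    def test_cadence_rises_then_falls(self):
        cadences = [
            np.mean([gait_profile_for_stage(s, k).cadence for k in range(10)])
            for s in range(6)
        ]
        peak = int(np.argmax(cadences))
        assert 0 < peak < 5
        assert cadences[5] < cadences[0]  # late-stage slowing below healthy

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            gait_profile_for_stage(6, 0)


class TestWalkTrace:
    def test_zero_jitter_gives_exact_spacing(self, layout, floor):
        profile = GaitProfile(
            cadence=120.0, step_time_jitter_sd=0.0,
            left_right_amplitude_ratio=1.0,
            contact_type_probs=(1.0, 0.0, 0.0),
        )
        trace = generate_walk_trace(profile, 6, layout, floor, 0.0, 0)
        np.testing.assert_allclose(np.diff(trace.annotations.strike_times), 0.5)

    def test_silence_without_steps_or_noise(self, layout, floor):
        trace = generate_walk_trace(
            gait_profile_for_stage(0, 0), 0, layout, floor, 0.0, 0
        )
        for rec in trace.recordings:
            assert np.all(rec.samples == 0)

    def test_nearer_sensor_sees_larger_amplitude(self, floor):
        layout = SensorLayout(positions=(0.0, 5.0), sampling_rate=500.0)
        profile = gait_profile_for_stage(0, 3)
        trace = generate_walk_trace(profile, 1, layout, floor, 0.0, 3)
        # single footstep lands near x=-0.5: sensor 0 is closer
        a0 = np.abs(trace.recordings[0].samples).max()
        a1 = np.abs(trace.recordings[1].samples).max()
        assert a0 > a1

    def test_noise_reference_is_clean_lead(self, layout, floor):
        trace = generate_walk_trace(
            gait_profile_for_stage(1, 2), 8, layout, floor, 0.05, 2
        )
        rec = trace.recordings[0]
        a, b = rec.noise_reference
        assert (b - a) / rec.sampling_rate >= 2.0
        assert b / rec.sampling_rate < trace.annotations.strike_times[0]

    def test_empty_layout_rejected(self, floor):
        with pytest.raises(ValueError):
            SensorLayout(positions=())


class TestDistractors:
    def test_no_kinds_is_identity(self, layout, floor):
        trace = generate_walk_trace(gait_profile_for_stage(0, 1), 5, layout, floor, 0.01, 1)
        rec = trace.recordings[0]
        assert inject_distractors(rec, [], 0) is rec

    def test_intervals_logged_and_superimposed(self, layout, floor):
        trace = generate_walk_trace(gait_profile_for_stage(0, 1), 5, layout, floor, 0.01, 1)
        rec = trace.recordings[0]
        kinds = ["isolated_impulse", "long_transient", "short_blip"]
        out = inject_distractors(rec, kinds, 7)
        assert [k for _, _, k in out.distractor_intervals] == kinds
        assert out.samples.size > rec.samples.size
        for a, b, kind in out.distractor_intervals:
            seg = out.samples[int(a * rec.sampling_rate): int(b * rec.sampling_rate)]
            assert np.abs(seg).max() > 5 * 0.01  # clearly above the noise floor
        durations = [b - a for a, b, _ in out.distractor_intervals]
        assert 0.2 <= durations[0] <= 0.6  # footstep-like but isolated
        assert durations[1] > 0.6
        assert durations[2] < 0.2

    def test_unknown_kind_rejected(self, layout, floor):
        trace = generate_walk_trace(gait_profile_for_stage(0, 1), 5, layout, floor, 0.01, 1)
        with pytest.raises(ValueError):
            inject_distractors(trace.recordings[0], ["earthquake"], 0)


class TestCohort:
    def test_functional_scale_round_trip(self, small_cohort):
        for subject in small_cohort:
            result = stage_for_subject(subject.biometrics, subject.run_time_100m)
            assert result.stage == subject.stage

    def test_trace_counts_within_range(self, layout, floor):
        cohort = generate_cohort(
            6, np.full(6, 1 / 6), (5, 10), 3, layout=layout, floor=floor,
            noise_sd=0.0, n_steps_range=(4, 5),
        )
        assert all(5 <= len(s.traces) <= 10 for s in cohort)

    def test_seed_determinism(self, layout, floor):
        kw = dict(layout=layout, floor=floor, noise_sd=0.01, n_steps_range=(4, 5))
        a = generate_cohort(3, np.full(6, 1 / 6), (2, 3), 17, **kw)
        b = generate_cohort(3, np.full(6, 1 / 6), (2, 3), 17, **kw)
        for sa, sb in zip(a, b):
            assert sa.stage == sb.stage
            assert sa.biometrics == sb.biometrics
            for ta, tb in zip(sa.traces, sb.traces):
                np.testing.assert_array_equal(
                    ta.recordings[0].samples, tb.recordings[0].samples
                )

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, [0.5, 0.5], (2, 3), 0)


def test_floor_model_validation():
    with pytest.raises(ValueError):
        FloorModel(natural_frequency=40.0)
    with pytest.raises(ValueError):
        FloorModel(damping_ratio=1.5)
    floor = FloorModel(attenuation_rate=0.5)
    assert floor.attenuation(2.0) < floor.attenuation(1.0) < floor.attenuation(0.0) == 1.0
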