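import numpy as np
import pytest
from scipy.stats import chi2

from walkbout import ParameterError, detect, detrend, magnitude, personal_threshold
from walkbout.simulate import (
    ScenarioSpec,
    Segment,
    build_scenario,
    calibration_day,
    corridor_protocol,
    gen_stationary,
    gen_transition,
    gen_walk,
    halting_gait_scenario,
    make_cohort,
    shuffling_scenario,
    slow_gait_scenario,
    stationary_day,
    transition_scenario,
)

FS = 100.0


class TestSegmentGenerators:
    def test_noiseless_stationary_detrends_to_zero(self):
        xyz = gen_stationary(60.0, gravity_dir=(0, 0, 1))
        from walkbout import AccelTrace

        mag = magnitude(detrend(AccelTrace(xyz, FS)))
        assert np.max(mag.values[100:-100]) < 1e-6

    def test_stationary_noise_magnitude_has_chi3_median(self, rng):
        sigma = 0.01
        xyz = gen_stationary(600.0, noise_sigma_g=sigma, rng=rng)
        from walkbout import AccelTrace

        mag = magnitude(detrend(AccelTrace(xyz, FS)))
        expected = sigma * np.sqrt(chi2.ppf(0.5, 3))
        assert np.median(mag.values) == pytest.approx(expected, rel=0.05)

    def test_walk_amplitude_bounds_respected(self):
        xyz = gen_walk(30.0, amp_g=0.15, step_hz=2.0)
        assert np.max(np.linalg.norm(xyz - [0, 0, 1], axis=1)) < 0.15 * 1.7

    def test_walk_pause_silences_envelope(self):
        xyz = gen_walk(
            30.0, amp_g=0.2, pauses=((10.0, 5.0),), phase_jitter=0.0
        )
        pause = slice(int(11 * FS), int(14 * FS))
        assert np.max(np.abs(xyz[pause] - [0, 0, 1])) < 1e-12

    def test_walk_rejects_out_of_band_cadence(self):
        with pytest.raises(ParameterError, match="step_hz"):
            gen_walk(10.0, step_hz=5.0)

    def test_transition_is_biphasic_with_cancelling_area(self):
        xyz = gen_transition(1.5, peak_g=0.8)
        vert = xyz[:, 2] - 1.0
        assert vert.max() == pytest.approx(0.8, rel=1e-6)
        assert vert.min() < -0.3
        assert abs(vert.sum()) / np.abs(vert).sum() < 0.01

    def test_zero_amplitude_transition_is_flat(self):
        xyz = gen_transition(1.5, peak_g=0.0)
        np.testing.assert_allclose(xyz, np.tile([0, 0, 1.0], (150, 1)), atol=1e-12)


class TestBuildScenario:
    def test_identical_seed_gives_byte_identical_trace(self):
        spec = corridor_protocol(seed=9)
        a, b = build_scenario(spec), build_scenario(spec)
        assert a.trace.xyz.tobytes() == b.trace.xyz.tobytes()
        np.testing.assert_array_equal(a.truth.labels, b.truth.labels)

    def test_different_seed_changes_noise_not_structure(self):
        a = build_scenario(corridor_protocol(seed=1))
        b = build_scenario(corridor_protocol(seed=2))
        assert a.segment_table == b.segment_table
        assert a.trace.xyz.tobytes() != b.trace.xyz.tobytes()

    def test_truth_marks_exactly_the_walk_segments(self):
        lt = build_scenario(corridor_protocol(seed=4))
        expected = np.zeros(lt.trace.n, dtype=np.uint8)
        walks = [t for t in lt.segment_table if t[0] == "walk"]
        assert len(walks) == 2
        for _, s, e in walks:
            expected[s:e] = 1
        np.testing.assert_array_equal(lt.truth.labels, expected)

    def test_segment_table_tiles_the_trace(self):
        lt = build_scenario(halting_gait_scenario(seed=1))
        cursor = 0
        for _, s, e in lt.segment_table:
            assert s == cursor and e > s
            cursor = e
        assert cursor == lt.trace.n

    def test_orientation_changes_axes_but_not_detection(self, rng):
        from scipy.stats import special_ortho_group

        R = special_ortho_group.rvs(3, random_state=rng)
        spec = corridor_protocol(seed=6)
        plain = build_scenario(spec)
        tilted = build_scenario(
            ScenarioSpec(
                segments=spec.segments, fs=spec.fs, orientation=R,
                noise_sigma_g=spec.noise_sigma_g, seed=spec.seed,
            )
        )
        assert not np.allclose(plain.trace.xyz, tilted.trace.xyz)
        b_plain, _ = detect(plain.trace)
        b_tilt, _ = detect(tilted.trace)
        assert b_plain.of_kind("walking").bouts == b_tilt.of_kind("walking").bouts

    def test_invalid_rotation_rejected(self):
        spec = corridor_protocol(seed=0)
        bad = np.eye(3) * 2.0
        with pytest.raises(ParameterError, match="rotation"):
            build_scenario(
                ScenarioSpec(segments=spec.segments, orientation=bad, seed=0)
            )


class TestScenarioBehaviours:
    """Each known failure mode has a scenario, and the detector responds
    to it the way the staged thresholds dictate."""

    def test_clean_walk_burst_detected_as_one_bout(self):
        lt = build_scenario(slow_gait_scenario(seed=5))
        bouts, _ = detect(lt.trace)
        assert len(bouts.walking) == 1

    def test_subthreshold_walk_not_detected(self):
        spec = ScenarioSpec(
            segments=(
                Segment("stationary", 40.0),
                Segment("walk", 30.0, {"step_hz": 1.0, "amp_g": 0.02}),
                Segment("stationary", 40.0),
            ),
            noise_sigma_g=0.005, seed=5,
        )
        bouts, _ = detect(build_scenario(spec).trace)
        assert len(bouts.walking) == 0

    def test_shuffling_scenario_is_a_miss_by_design(self):
        bouts, _ = detect(build_scenario(shuffling_scenario(seed=2)).trace)
        assert len(bouts.walking) == 0

    def test_halting_gait_with_long_stop_splits_the_bout(self):
        lt = build_scenario(halting_gait_scenario(seed=3, pause_s=3.0))
        bouts, _ = detect(lt.trace)
        assert len(bouts.walking) == 2

    def test_isolated_high_transition_rejected_by_heuristic(self):
        lt = build_scenario(transition_scenario(peak_g=0.8, duration_s=1.0, seed=1))
        bouts, labels = detect(lt.trace)
        assert len(bouts.walking) == 0
        assert any(b.kind == "rejected_transition" for b in bouts)
        assert labels.labels.sum() == 0

    def test_low_slow_transition_survives_heuristic_but_fails_duration(self):
        spec = ScenarioSpec(
            segments=(
                Segment("stationary", 30.0),
                Segment("transition", 1.5, {"peak_g": 0.3}),
                Segment("stationary", 30.0),
            ),
            noise_sigma_g=0.005, seed=1,
        )
        bouts, labels = detect(build_scenario(spec).trace)
        assert len(bouts.walking) == 0
        kinds = {b.kind for b in bouts if b.n_frames > 20}
        assert kinds == {"rejected_short"}


class TestDayGenerators:
    def test_stationary_day_activity_fraction_bounded(self):
        spec = stationary_day(0.01, hours=0.2, activity_fraction=0.04, seed=1)
        lt = build_scenario(spec)
        walk = sum(e - s for k, s, e in lt.segment_table if k == "walk")
        assert walk / lt.trace.n == pytest.approx(0.04, abs=0.005)

    def test_calibration_day_median_exceeds_generic_threshold(self):
        day = build_scenario(calibration_day(active_sigma_g=0.06, hours=2.0, seed=8)).trace
        cal = personal_threshold(day, min_hours=1.0)
        assert 0.05 < cal.value_g < 0.12

    def test_cohort_is_reproducible_and_sized(self):
        a = make_cohort(n_participants=3, seed=5)
        b = make_cohort(n_participants=3, seed=5)
        assert [p.participant_id for p in a] == ["P01", "P02", "P03"]
        for pa, pb in zip(a, b):
            assert pa.corridor.trace.xyz.tobytes() == pb.corridor.trace.xyz.tobytes()
            assert pa.day_seed == pb.day_seed
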