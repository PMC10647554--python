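import numpy as np
import pytest
from scipy.stats import special_ortho_group
from sklearn.base import clone

from walkbout import (
    AccelTrace,
    ActivitySignal,
    Bout,
    BoutSet,
    ContractViolationError,
    DetectorConfig,
    LabelSeries,
    ParameterError,
    StageError,
    WalkingBoutDetector,
    binarize,
    default_kernel,
    detect,
    enforce_min_duration,
    filter_gaps,
    find_gaps,
    gaussian_smooth,
    reject_transitions,
)
from walkbout.simulate import ScenarioSpec, Segment, build_scenario

FS = 100.0
CFG = DetectorConfig.generic()


def sig(values):
    return ActivitySignal(np.asarray(values, dtype=float), FS)


def labels(bits):
    return LabelSeries(np.asarray(bits, dtype=np.uint8), FS)


class TestBinarize:
    def test_strictly_above_threshold(self):
        out = binarize(sig([0.01, 0.06, 0.05]), 0.05)
        np.testing.assert_array_equal(out.labels, [0, 1, 0])

    def test_all_zero_signal(self):
        assert binarize(sig(np.zeros(10)), 0.05).labels.sum() == 0

    def test_scale_equivariant(self, rng):
        v = rng.uniform(0, 0.2, 500)
        np.testing.assert_array_equal(
            binarize(sig(v), 0.05).labels, binarize(sig(2 * v), 0.10).labels
        )


class TestFindGaps:
    def test_single_interior_gap(self):
        gaps = find_gaps(labels([1, 1, 0, 0, 0, 1]))
        assert [(g.start_frame, g.end_frame) for g in gaps] == [(2, 5)]

    def test_all_ones_gives_no_gaps(self):
        assert len(find_gaps(labels(np.ones(20)))) == 0

    def test_all_zeros_gives_one_boundary_gap(self):
        gaps = find_gaps(labels(np.zeros(20)))
        assert [(g.start_frame, g.end_frame) for g in gaps] == [(0, 20)]


class TestFilterGaps:
    def make(self, lab):
        return find_gaps(labels(lab))

    def test_long_low_likelihood_gap_splits_activity(self):
        lab = np.r_[np.ones(100), np.zeros(300), np.ones(100)]
        lik = sig(lab.astype(float))  # likelihood 0 in the gap
        act = filter_gaps(self.make(lab), lik, CFG)
        assert [(b.start_frame, b.end_frame) for b in act] == [(0, 100), (400, 500)]

    def test_short_high_likelihood_gap_is_absorbed(self):
        lab = np.r_[np.ones(100), np.zeros(30), np.ones(100)]
        lik = sig(np.ones(230) * 0.5)
        act = filter_gaps(self.make(lab), lik, CFG)
        assert [(b.start_frame, b.end_frame) for b in act] == [(0, 230)]

    def test_boundary_gaps_always_retained(self):
        lab = np.r_[np.zeros(10), np.ones(50), np.zeros(10)]
        lik = sig(np.ones(70))  # would be absorbed were it interior
        act = filter_gaps(self.make(lab), lik, CFG)
        assert [(b.start_frame, b.end_frame) for b in act] == [(10, 60)]

    def test_gap_between_bursts_depends_on_min_gap_threshold(self):
        # A 125-frame gap between two long bursts: with the default 2 s
        # Gaussian kernel exactly 57 gap samples fall below likelihood 0.2
        # (computed directly from the smoothed series), so the gap is kept
        # with min_gap=50 (two bouts) and absorbed with min_gap=100 (one).
        lab = np.r_[np.ones(400), np.zeros(125), np.ones(400)]
        lik = gaussian_smooth(sig(lab.astype(float)), default_kernel(FS))
        count = int(np.sum(lik.values[400:525] < 0.2))
        assert count == 57
        gaps = self.make(lab)
        two = filter_gaps(gaps, lik, DetectorConfig.generic(min_gap_frames=50))
        one = filter_gaps(gaps, lik, DetectorConfig.generic(min_gap_frames=100))
        assert len(two) == 2 and len(one) == 1

    def test_likelihood_outside_unit_interval_rejected(self):
        lab = np.r_[np.ones(10), np.zeros(10), np.ones(10)]
        with pytest.raises(ContractViolationError, match="likelihood"):
            filter_gaps(self.make(lab), sig(np.full(30, 1.5)), CFG)


class TestRejectTransitions:
    def bouts(self, *ivals, n=1000):
        return BoutSet(tuple(Bout(s, e, "activity") for s, e in ivals), n, FS)

    def test_quiet_bout_is_walking(self):
        sm = sig(np.full(1000, 0.1))
        out = reject_transitions(self.bouts((100, 300)), sm, CFG)
        assert out.bouts[0].kind == "walking"

    def test_high_intensity_bout_rejected(self):
        v = np.full(1000, 0.1)
        v[100:110] = 0.5  # 10 of 100 frames above 0.4 g
        out = reject_transitions(self.bouts((50, 150)), sig(v), CFG)
        assert out.bouts[0].kind == "rejected_transition"

    def test_exact_boundary_fraction_is_rejected(self):
        v = np.full(1000, 0.1)
        v[:25] = 0.5  # exactly 25/1000 = 2.5%
        out = reject_transitions(self.bouts((0, 1000)), sig(v), CFG)
        assert out.bouts[0].kind == "rejected_transition"


class TestEnforceMinDuration:
    def walking(self, *ivals, n=2000):
        return BoutSet(tuple(Bout(s, e, "walking") for s, e in ivals), n, FS)

    def test_bout_shorter_than_2s_rejected(self):
        out = enforce_min_duration(self.walking((0, 150)), CFG)
        assert out.bouts[0].kind == "rejected_short"

    def test_exactly_2s_bout_kept(self):
        out = enforce_min_duration(self.walking((0, 200)), CFG)
        assert out.bouts[0].kind == "walking"

    def test_empty_set_passes_through(self):
        assert len(enforce_min_duration(self.walking(), CFG)) == 0


class TestDetectEndToEnd:
    def test_stationary_trace_has_no_walking(self, rng):
        tr = AccelTrace(rng.normal(0, 0.005, (30000, 3)) + [0, 0, 1], FS)
        bouts, lab = detect(tr)
        assert len(bouts.walking) == 0
        assert lab.labels.sum() == 0

    def test_single_burst_detected_with_tight_boundaries(self):
        spec = ScenarioSpec(
            segments=(
                Segment("stationary", 60.0),
                Segment("walk", 30.0, {"step_hz": 2.0, "amp_g": 0.15,
                                       "harmonic_ratio": 0.0, "lateral_ratio": 0.0,
                                       "phase_jitter": 0.0, "ramp_s": 0.0}),
                Segment("stationary", 60.0),
            ),
            noise_sigma_g=0.005, seed=7,
        )
        lt = build_scenario(spec)
        bouts, _ = detect(lt.trace)
        walking = list(bouts.walking)
        assert len(walking) == 1
        (start, end), = [(b.start_frame, b.end_frame) for b in walking]
        seg = next(t for t in lt.segment_table if t[0] == "walk")
        assert abs(start - seg[1]) <= 0.5 * FS
        assert abs(end - seg[2]) <= 0.5 * FS

    def test_rotation_leaves_bouts_identical(self, corridor, rng):
        base, _ = detect(corridor.trace)
        R = special_ortho_group.rvs(3, random_state=rng)
        rotated, _ = detect(corridor.trace.rotated(R))
        assert rotated.bouts == base.bouts

    def test_deterministic(self, corridor):
        a, la = detect(corridor.trace)
        b, lb = detect(corridor.trace)
        assert a.bouts == b.bouts
        np.testing.assert_array_equal(la.labels, lb.labels)

    def test_walking_bouts_lie_within_activity_bouts(self, corridor):
        from walkbout import preprocess
        cfg = CFG
        kernel = default_kernel(FS)
        detr = preprocess.detrend(corridor.trace)
        mag = preprocess.magnitude(detr)
        binary = binarize(mag, cfg.activity_threshold_g)
        lik = gaussian_smooth(
            ActivitySignal(binary.labels.astype(float), FS), kernel
        )
        activity = filter_gaps(find_gaps(binary), lik, cfg)
        ivals = [(b.start_frame, b.end_frame) for b in activity]
        final, _ = detect(corridor.trace, cfg)
        for b in final.walking:
            assert sum(
                s <= b.start_frame and b.end_frame <= e for s, e in ivals
            ) == 1

    def test_stage_errors_are_annotated(self):
        tr = AccelTrace(np.zeros((40, 3)), FS)  # too short to detrend
        with pytest.raises(StageError, match="detrend"):
            detect(tr)


class TestConfig:
    def test_personalized_defaults_switch_min_gap(self):
        cfg = DetectorConfig.personalized(0.07)
        assert cfg.min_gap_frames == 100 and cfg.mode == "personalized"

    def test_frame_threshold_rescales_with_fs(self):
        assert CFG.effective_min_gap(100.0) == 50
        assert CFG.effective_min_gap(50.0) == 25

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"likelihood_threshold": 1.5},
            {"activity_threshold_g": 0.5},  # >= heuristic threshold
            {"min_gap_frames": 0},
            {"min_bout_seconds": -1.0},
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ParameterError):
            DetectorConfig.generic(**kwargs)


class TestEstimator:
    def test_generic_fit_freezes_population_threshold(self):
        det = WalkingBoutDetector().fit()
        assert det.threshold_g_ == pytest.approx(0.05)
        assert det.min_gap_frames_ == 50

    def test_predict_matches_functional_pipeline(self, corridor):
        det = WalkingBoutDetector().fit()
        pred = det.predict(corridor.trace)
        _, lab = detect(corridor.trace)
        np.testing.assert_array_equal(pred, lab.labels)

    def test_accepts_plain_arrays(self, corridor):
        det = WalkingBoutDetector(fs=FS).fit()
        pred = det.predict(corridor.trace.xyz)
        assert pred.shape == (corridor.trace.n,)

    def test_sklearn_clone_roundtrip(self):
        det = WalkingBoutDetector(activity_threshold_g=0.07, mode="generic")
        cloned = clone(det)
        assert cloned.get_params() == det.get_params()

    def test_personalized_requires_calibration_trace(self):
        with pytest.raises(ParameterError, match="calibration"):
            WalkingBoutDetector(mode="personalized").fit()

    def test_unfitted_predict_raises(self, corridor):
        with pytest.raises(ParameterError, match="not fitted"):
            WalkingBoutDetector().predict(corridor.trace)

    def test_score_is_per_sample_accuracy(self, corridor):
        det = WalkingBoutDetector().fit()
        acc = det.score(corridor.trace, corridor.truth.labels)
        assert 0.9 < acc <= 1.0
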