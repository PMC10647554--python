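"""Staged walking-bout classification on the detrended 3D magnitude.

The pipeline:

1. binarize — compare the detrended magnitude to the activity threshold
   (generic 0.05 g or a personalized 24-h median), giving a 0/1 series.
2. smooth the binary series into an "activity likelihood" in [0, 1].
3. find_gaps / filter_gaps — every maximal run of 0s is a candidate gap; a
   gap is kept as genuine non-activity only if enough of its samples have
   likelihood below 0.2 (50 frames generic, 100 personalized, at 100 Hz),
   otherwise it is absorbed into the surrounding activity.
4. reject_transitions — activity bouts in which 2.5% or more of the
   Gaussian-smoothed magnitude exceeds 0.4 g are high-intensity events
   (sit-stand transitions), not walking.
5. enforce_min_duration — walking bouts shorter than 2 s are rejected.

Rejected bouts are retained with their rejection kind for audit; only
``kind == "walking"`` contributes to the output label series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import preprocess
from .preprocess import SmoothingKernel, default_kernel, scale_frames
from .types import (
    AccelTrace,
    ActivitySignal,
    Bout,
    BoutSet,
    ContractViolationError,
    LabelSeries,
    ParameterError,
    StageError,
    _runs_of,
)

__all__ = [
    "DetectorConfig",
    "binarize",
    "find_gaps",
    "filter_gaps",
    "reject_transitions",
    "enforce_min_duration",
    "detect",
    "detect_walking",
    "WalkingBoutDetector",
]

GENERIC_THRESHOLD_G = 0.05
GENERIC_MIN_GAP_FRAMES = 50
PERSONALIZED_MIN_GAP_FRAMES = 100


@dataclass(frozen=True)
class DetectorConfig:
    """All thresholds of the staged classifier.

    Frame counts (``min_gap_frames``) are defined at the nominal 100 Hz and
    rescaled by ``fs / 100`` when applied to a trace at another rate.
    """

    activity_threshold_g: float = GENERIC_THRESHOLD_G
    likelihood_threshold: float = 0.2
    min_gap_frames: int = GENERIC_MIN_GAP_FRAMES
    heuristic_threshold_g: float = 0.4
    heuristic_fraction: float = 0.025
    min_bout_seconds: float = 2.0
    mode: str = "generic"

    def __post_init__(self):
        if self.mode not in ("generic", "personalized"):
            raise ParameterError(f"mode must be generic or personalized, got {self.mode}")
        if not 0 < self.likelihood_threshold < 1:
            raise ParameterError(
                f"likelihood_threshold must be in (0, 1), got {self.likelihood_threshold}"
            )
        if not 0 < self.activity_threshold_g < self.heuristic_threshold_g:
            raise ParameterError(
                "need 0 < activity_threshold_g < heuristic_threshold_g, got "
                f"{self.activity_threshold_g} and {self.heuristic_threshold_g}"
            )
        if self.min_gap_frames < 1:
            raise ParameterError(f"min_gap_frames must be >= 1, got {self.min_gap_frames}")
        if not self.min_bout_seconds > 0:
            raise ParameterError(
                f"min_bout_seconds must be > 0, got {self.min_bout_seconds}"
            )
        if not 0 < self.heuristic_fraction < 1:
            raise ParameterError(
                f"heuristic_fraction must be in (0, 1), got {self.heuristic_fraction}"
            )

    @classmethod
    def generic(cls, **overrides) -> "DetectorConfig":
        return cls(mode="generic", **overrides)

    @classmethod
    def personalized(cls, activity_threshold_g: float, **overrides) -> "DetectorConfig":
        overrides.setdefault("min_gap_frames", PERSONALIZED_MIN_GAP_FRAMES)
        return cls(
            mode="personalized", activity_threshold_g=activity_threshold_g, **overrides
        )

    def effective_min_gap(self, fs: float) -> int:
        return scale_frames(self.min_gap_frames, fs)


def binarize(signal: ActivitySignal, threshold_g: float) -> LabelSeries:
    """1 where the signal is strictly above the threshold, else 0.

    A sample exactly at the threshold counts as inactive (conservative
    toward non-walking).
    """
    if not threshold_g > 0:
        raise ParameterError(f"threshold_g must be > 0, got {threshold_g}")
    return LabelSeries((signal.values > threshold_g).astype(np.uint8), signal.fs)


def find_gaps(labels: LabelSeries) -> BoutSet:
    """Maximal runs of 0s (periods of non-activity) as ``kind='gap'`` bouts."""
    runs = _runs_of(labels.labels, 0)
    return BoutSet(tuple(Bout(s, e, "gap") for s, e in runs), labels.n, labels.fs)


def filter_gaps(
    gaps: BoutSet, likelihood: ActivitySignal, cfg: DetectorConfig
) -> BoutSet:
    """Keep genuine gaps, absorb spurious ones; return the activity bouts.

    A gap is retained as non-activity iff the number of its samples with
    likelihood below ``cfg.likelihood_threshold`` reaches the minimum gap
    threshold (rescaled for fs). Gaps touching either end of the recording
    are always retained: there is no surrounding activity to absorb them
    into. The returned set is the complement of the retained gaps, as
    ``kind='activity'`` bouts.
    """
    if gaps.n != likelihood.n:
        raise ContractViolationError(
            f"gap set (n={gaps.n}) and likelihood (n={likelihood.n}) are misaligned"
        )
    v = likelihood.values
    if v.min() < -1e-9 or v.max() > 1 + 1e-9:
        raise ContractViolationError(
            "activity likelihood must lie in [0, 1]; got values in "
            f"[{v.min():.4g}, {v.max():.4g}]"
        )
    min_gap = cfg.effective_min_gap(likelihood.fs)
    retained = np.zeros(gaps.n, dtype=bool)
    for g in gaps:
        if g.kind != "gap":
            raise ContractViolationError(f"filter_gaps expects gap bouts, got {g.kind!r}")
        boundary = g.start_frame == 0 or g.end_frame == gaps.n
        count = int(np.sum(v[g.start_frame : g.end_frame] < cfg.likelihood_threshold))
        if boundary or count >= min_gap:
            retained[g.start_frame : g.end_frame] = True
    activity = _runs_of(retained, 0)
    return BoutSet(
        tuple(Bout(s, e, "activity") for s, e in activity), gaps.n, gaps.fs
    )


def reject_transitions(
    bouts: BoutSet, smoothed_mag: ActivitySignal, cfg: DetectorConfig
) -> BoutSet:
    """Classify each activity bout as walking or a high-intensity transition.

    A bout stays walking iff strictly less than ``cfg.heuristic_fraction``
    (2.5%) of its smoothed-magnitude samples exceed the 0.4 g heuristic
    threshold; otherwise it is a sit-stand-like event and is rejected.
    """
    if bouts.n != smoothed_mag.n:
        raise ContractViolationError(
            f"bout set (n={bouts.n}) and magnitude (n={smoothed_mag.n}) are misaligned"
        )
    out = []
    for b in bouts:
        if b.n_frames == 0:
            raise ContractViolationError("empty bout in reject_transitions")
        seg = smoothed_mag.values[b.start_frame : b.end_frame]
        frac = float(np.mean(seg > cfg.heuristic_threshold_g))
        kind = "walking" if frac < cfg.heuristic_fraction else "rejected_transition"
        out.append(replace(b, kind=kind))
    return BoutSet(tuple(out), bouts.n, bouts.fs)


def enforce_min_duration(bouts: BoutSet, cfg: DetectorConfig) -> BoutSet:
    """Reject walking bouts shorter than the minimum duration (2 s).

    A bout of exactly the minimum duration is kept.
    """
    out = []
    for b in bouts:
        if b.kind == "walking" and b.duration_s(bouts.fs) < cfg.min_bout_seconds:
            b = replace(b, kind="rejected_short")
        out.append(b)
    return BoutSet(tuple(out), bouts.n, bouts.fs)


def _stage(name: str):
    """Decorator-free stage wrapper: run fn, annotate errors with the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def detect(
    trace: AccelTrace,
    cfg: Optional[DetectorConfig] = None,
    kernel: Optional[SmoothingKernel] = None,
    cutoff_hz: float = 0.25,
    filter_order: int = 4,
) -> Tuple[BoutSet, LabelSeries]:
    """Run the full staged classification on a raw trace.

    Returns the audit :class:`BoutSet` (walking plus rejected bouts, with
    their rejection kinds) and the per-sample walking :class:`LabelSeries`
    derived from the surviving walking bouts only. The pipeline is fully
    deterministic.
    """
    cfg = cfg or DetectorConfig.generic()
    kernel = kernel or default_kernel(trace.fs)
    with _stage("detrend"):
        detrended = preprocess.detrend(trace, cutoff_hz=cutoff_hz, order=filter_order)
    with _stage("magnitude"):
        mag = preprocess.magnitude(detrended)
    with _stage("binarize"):
        binary = binarize(mag, cfg.activity_threshold_g)
    with _stage("likelihood"):
        likelihood = preprocess.gaussian_smooth(
            ActivitySignal(binary.labels.astype(np.float64), binary.fs), kernel
        )
    with _stage("find_gaps"):
        gaps = find_gaps(binary)
    with _stage("filter_gaps"):
        activity = filter_gaps(gaps, likelihood, cfg)
    with _stage("smooth_magnitude"):
        smoothed_mag = preprocess.gaussian_smooth(mag, kernel)
    with _stage("reject_transitions"):
        classified = reject_transitions(activity, smoothed_mag, cfg)
    with _stage("enforce_min_duration"):
        final = enforce_min_duration(classified, cfg)
    return final, final.to_labels(("walking",))


class WalkingBoutDetector(BaseEstimator):
    """Threshold-based walking-bout detector for lower-back accelerometry.

    A scikit-learn-style estimator over the staged pipeline. In generic
    mode :meth:`fit` requires no data and freezes the 0.05 g population
    threshold; in personalized mode :meth:`fit` takes a roughly 24-h
    free-living trace and replaces the threshold with the median of its
    detrended 3D magnitude, switching the minimum gap threshold from 50 to
    100 frames.

    Parameters
    ----------
    mode : {'generic', 'personalized'}
    activity_threshold_g : float
        Minimum detrended 3D magnitude for any activity (generic mode).
    likelihood_threshold : float
        Level below which a smoothed-binary sample counts as inactive.
    min_gap_frames : int or None
        Minimum gap threshold at 100 Hz; None selects the mode default
        (50 generic, 100 personalized).
    heuristic_threshold_g, heuristic_fraction : float
        Smoothed-magnitude level and bout fraction above which a bout is a
        high-intensity transition rather than walking.
    min_bout_seconds : float
        Shortest admissible walking bout.
    cutoff_hz, filter_order : float, int
        Detrending low-pass parameters.
    smooth_window_s, smooth_sigma_divisor : float
        Gaussian kernel span in seconds and the window/sigma ratio.
    fs : float
        Sampling rate assumed when raw arrays (rather than
        :class:`AccelTrace`) are passed.
    calibration_min_hours : float
        Shortest calibration trace accepted by personalized fit.

    Attributes
    ----------
    threshold_g_ : float
        Activity threshold actually applied after fit.
    min_gap_frames_ : int
        Minimum gap threshold (at 100 Hz) actually applied after fit.
    config_ : DetectorConfig
        Frozen stage configuration used by predict/detect.
    calibration_ : PersonalThreshold or None
        Calibration record when mode='personalized'.
    """

    def __init__(
        self,
        mode: str = "generic",
        activity_threshold_g: float = GENERIC_THRESHOLD_G,
        likelihood_threshold: float = 0.2,
        min_gap_frames: Optional[int] = None,
        heuristic_threshold_g: float = 0.4,
        heuristic_fraction: float = 0.025,
        min_bout_seconds: float = 2.0,
        cutoff_hz: float = 0.25,
        filter_order: int = 4,
        smooth_window_s: float = 2.0,
        smooth_sigma_divisor: float = 5.0,
        fs: float = 100.0,
        calibration_min_hours: float = 20.0,
    ):
        self.mode = mode
        self.activity_threshold_g = activity_threshold_g
        self.likelihood_threshold = likelihood_threshold
        self.min_gap_frames = min_gap_frames
        self.heuristic_threshold_g = heuristic_threshold_g
        self.heuristic_fraction = heuristic_fraction
        self.min_bout_seconds = min_bout_seconds
        self.cutoff_hz = cutoff_hz
        self.filter_order = filter_order
        self.smooth_window_s = smooth_window_s
        self.smooth_sigma_divisor = smooth_sigma_divisor
        self.fs = fs
        self.calibration_min_hours = calibration_min_hours

    # -- helpers -----------------------------------------------------------
    def _as_trace(self, X) -> AccelTrace:
        if isinstance(X, AccelTrace):
            return X
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ParameterError(
                f"X must be an AccelTrace or array of shape (n, 3), got {arr.shape}"
            )
        return AccelTrace(arr, self.fs)

    def _kernel(self, fs: float) -> SmoothingKernel:
        return default_kernel(fs, self.smooth_window_s, self.smooth_sigma_divisor)

    # -- estimator API -----------------------------------------------------
    def fit(self, X=None, y=None) -> "WalkingBoutDetector":
        """Freeze the stage configuration; calibrate if personalized.

        In personalized mode ``X`` is the ~24-h calibration trace; ``y`` is
        ignored (the method is unsupervised).
        """
        from .personalize import personal_threshold  # local import: cycle

        if self.mode == "generic":
            self.threshold_g_ = float(self.activity_threshold_g)
            self.min_gap_frames_ = int(
                self.min_gap_frames
                if self.min_gap_frames is not None
                else GENERIC_MIN_GAP_FRAMES
            )
            self.calibration_ = None
        elif self.mode == "personalized":
            if X is None:
                raise ParameterError(
                    "personalized mode requires a calibration trace in fit(X)"
                )
            cal = personal_threshold(
                self._as_trace(X),
                min_hours=self.calibration_min_hours,
                cutoff_hz=self.cutoff_hz,
                order=self.filter_order,
            )
            self.threshold_g_ = cal.value_g
            self.min_gap_frames_ = int(
                self.min_gap_frames
                if self.min_gap_frames is not None
                else PERSONALIZED_MIN_GAP_FRAMES
            )
            self.calibration_ = cal
        else:
            raise ParameterError(f"unknown mode {self.mode!r}")
        self.config_ = DetectorConfig(
            activity_threshold_g=self.threshold_g_,
            likelihood_threshold=self.likelihood_threshold,
            min_gap_frames=self.min_gap_frames_,
            heuristic_threshold_g=self.heuristic_threshold_g,
            heuristic_fraction=self.heuristic_fraction,
            min_bout_seconds=self.min_bout_seconds,
            mode=self.mode,
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "config_"):
            raise ParameterError(
                "this WalkingBoutDetector instance is not fitted yet; call fit first"
            )

    def detect(self, X) -> Tuple[BoutSet, LabelSeries]:
        """Full audit output: bout set (with rejection kinds) and labels."""
        self._check_fitted()
        trace = self._as_trace(X)
        return detect(
            trace,
            self.config_,
            kernel=self._kernel(trace.fs),
            cutoff_hz=self.cutoff_hz,
            filter_order=self.filter_order,
        )

    def predict(self, X) -> np.ndarray:
        """Per-sample walking labels (1 = walking) as a numpy array."""
        _, labels = self.detect(X)
        return labels.labels.astype(np.int64)

    def score(self, X, y) -> float:
        """Per-sample accuracy against a ground-truth 0/1 stream."""
        y = np.asarray(y)
        pred = self.predict(X)
        if y.shape != pred.shape:
            raise ParameterError(f"y has shape {y.shape}, expected {pred.shape}")
        return float(np.mean(pred == y))


def detect_walking(
    trace: AccelTrace, mode: str = "generic", calibration_trace=None, **params
) -> Tuple[BoutSet, LabelSeries]:
    """Convenience wrapper: fit a :class:`WalkingBoutDetector` and run it."""
    det = WalkingBoutDetector(mode=mode, fs=trace.fs, **params)
    det.fit(calibration_trace)
    return det.detect(trace)
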