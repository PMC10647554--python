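"""Personalized activity threshold from a 24-h free-living recording.

Over a full day a wearer is stationary more often than moving, so the
median of the detrended 3D magnitude sits at the individual's baseline of
no movement and can replace the generic 0.05 g threshold. The median is
taken on the *detrended* magnitude: that is the signal the threshold is
compared against downstream (a raw-magnitude median would sit near 1 g,
dominated by gravity, and be useless as an activity threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import preprocess
from .detector import DetectorConfig
from .types import AccelTrace, CalibrationError

__all__ = [
    "PersonalThreshold",
    "personal_threshold",
    "choose_calibration_day",
    "personalized_config",
]

#: plausibility band for a resting-baseline threshold, in g
SANITY_MIN_G = 0.0
SANITY_MAX_G = 0.5


@dataclass(frozen=True)
class PersonalThreshold:
    """A calibrated per-wearer activity threshold.

    ``source_window`` is the (start_hour, end_hour) interval of the
    calibration segment relative to the start of its recording.
    """

    value_g: float
    source_window: Tuple[float, float]
    n_samples_used: int

    def __post_init__(self):
        if not SANITY_MIN_G < self.value_g < SANITY_MAX_G:
            raise CalibrationError(
                f"personal threshold {self.value_g:.4g} g outside the plausible "
                f"({SANITY_MIN_G}, {SANITY_MAX_G}) g band"
            )


def personal_threshold(
    day_trace: AccelTrace,
    min_hours: float = 20.0,
    cutoff_hz: float = 0.25,
    order: int = 4,
) -> PersonalThreshold:
    """Median of the detrended 3D magnitude over a (nominally 24-h) day.

    Parameters
    ----------
    day_trace : AccelTrace
        Free-living calibration segment; must span at least ``min_hours``
        (default 20, tolerating minor data loss within a day).
    min_hours : float
        Shortest accepted calibration window. Lower it deliberately for
        scaled-down experiments; the median of a stationary-dominated trace
        has the same distribution regardless of duration.

    Raises
    ------
    CalibrationError
        If the window is too short ("insufficient calibration data") or
        the resulting value falls outside the (0, 0.5) g plausibility band.
    """
    hours = day_trace.duration_s / 3600.0
    if hours < min_hours:
        raise CalibrationError(
            f"insufficient calibration data: {hours:.2f} h < {min_hours} h required"
        )
    detrended = preprocess.detrend(day_trace, cutoff_hz=cutoff_hz, order=order)
    mag = preprocess.magnitude(detrended)
    value = float(np.median(mag.values))
    if not SANITY_MIN_G < value < SANITY_MAX_G:
        raise CalibrationError(
            f"calibration quality: median magnitude {value:.4g} g outside the "
            f"plausible ({SANITY_MIN_G}, {SANITY_MAX_G}) g band"
        )
    return PersonalThreshold(
        value_g=value, source_window=(0.0, hours), n_samples_used=day_trace.n
    )


def choose_calibration_day(week_trace: AccelTrace, day_index: int) -> AccelTrace:
    """Extract the 24-h segment ``[day_index*24h, (day_index+1)*24h)``.

    Day boundaries are wear-time relative (hours since the recording
    started), not calendar midnight. ``day_index`` is 0-based, so the third
    day of wear — a day on which participants have acclimated to the sensor
    and which is typically free of data loss — is ``day_index=2``.
    """
    if day_index < 0:
        raise CalibrationError(f"day_index must be >= 0, got {day_index}")
    frames_per_day = int(round(24 * 3600 * week_trace.fs))
    start = day_index * frames_per_day
    end = min((day_index + 1) * frames_per_day, week_trace.n)
    if start >= week_trace.n:
        raise CalibrationError(
            f"day {day_index} starts beyond the recording "
            f"({week_trace.duration_s / 86400:.2f} days long)"
        )
    return week_trace.slice_frames(start, end)


def personalized_config(
    day_trace: AccelTrace,
    fallback: bool = False,
    min_hours: float = 20.0,
    **config_overrides,
) -> Tuple[DetectorConfig, Optional[PersonalThreshold]]:
    """Calibrate and build the personalized detector configuration.

    With ``fallback=True`` a failed calibration emits a warning and returns
    the generic configuration instead of raising, so a bad calibration day
    can never silently change detection semantics.
    """
    try:
        cal = personal_threshold(day_trace, min_hours=min_hours)
    except CalibrationError as err:
        if not fallback:
            raise
        warnings.warn(
            f"personalized calibration failed ({err}); falling back to the "
            "generic configuration",
            stacklevel=2,
        )
        return DetectorConfig.generic(**config_overrides), None
    return DetectorConfig.personalized(cal.value_g, **config_overrides), cal
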