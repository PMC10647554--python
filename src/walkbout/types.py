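"""Core containers for the detection pipeline.

All series share one time base: a trace of ``n`` samples at ``fs`` Hz,
indexed by 0-based frame number. Intervals are half-open ``[start, end)``
and durations are ``(end - start) / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "AccelTrace",
    "ActivitySignal",
    "LabelSeries",
    "Bout",
    "BoutSet",
    "WalkboutError",
    "ParameterError",
    "TraceTooShortError",
    "CalibrationError",
    "AlignmentError",
    "ContractViolationError",
    "StageError",
]


class WalkboutError(Exception):
    """Base class for package errors."""


class ParameterError(WalkboutError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class TraceTooShortError(WalkboutError, ValueError):
    """The trace is too short for stable zero-phase filtering."""


class CalibrationError(WalkboutError, ValueError):
    """Personalized calibration failed (insufficient or implausible data)."""


class AlignmentError(WalkboutError, ValueError):
    """Two series that must share a time base do not."""


class ContractViolationError(WalkboutError, ValueError):
    """An inter-stage contract was violated (e.g. likelihood outside [0, 1])."""


class StageError(WalkboutError, RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class AccelTrace:
    """Triaxial linear acceleration in units of g at a fixed sampling rate.

    Parameters
    ----------
    xyz : ndarray of shape (n, 3)
        Per-sample acceleration ``(ax, ay, az)`` in g.
    fs : float
        Sampling rate in Hz (nominally 100).
    t0 : float or str, optional
        Clock time of the first sample (seconds since epoch or ISO string);
        informational only.
    """

    xyz: np.ndarray
    fs: float
    t0: Optional[object] = None

    def __post_init__(self):
        arr = np.asarray(self.xyz, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ParameterError(f"xyz must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ParameterError("trace must contain at least one sample")
        if not float(self.fs) > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0])
            raise ParameterError(f"non-finite acceleration value at frame {bad}")
        object.__setattr__(self, "xyz", arr)
        object.__setattr__(self, "fs", float(self.fs))

    @classmethod
    def from_axes(cls, ax, ay, az, fs: float, t0=None) -> "AccelTrace":
        ax = _as_float_array(ax, "ax")
        ay = _as_float_array(ay, "ay")
        az = _as_float_array(az, "az")
        if not (len(ax) == len(ay) == len(az)):
            raise ParameterError("ax, ay, az must have equal length")
        return cls(np.column_stack([ax, ay, az]), fs, t0)

    @property
    def n(self) -> int:
        return self.xyz.shape[0]

    @property
    def ax(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def ay(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def az(self) -> np.ndarray:
        return self.xyz[:, 2]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def rotated(self, rotation: np.ndarray) -> "AccelTrace":
        """Return the trace as seen by a sensor rotated by ``rotation``.

        ``rotation`` must be a proper orthonormal 3x3 matrix.
        """
        R = np.asarray(rotation, dtype=np.float64)
        if R.shape != (3, 3):
            raise ParameterError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ParameterError("rotation must be orthonormal")
        return replace(self, xyz=self.xyz @ R.T)

    def slice_frames(self, start: int, end: int) -> "AccelTrace":
        if not (0 <= start < end <= self.n):
            raise ParameterError(f"invalid frame slice [{start}, {end}) for n={self.n}")
        return replace(self, xyz=self.xyz[start:end])


@dataclass(frozen=True)
class ActivitySignal:
    """A single nonnegative per-sample series on a trace's time base.

    Either the detrended 3D magnitude (units g) or a smoothed, dimensionless
    companion such as the activity likelihood.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self):
        arr = _as_float_array(self.values, "values")
        if arr.shape[0] < 1:
            raise ParameterError("signal must contain at least one sample")
        if not float(self.fs) > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LabelSeries:
    """Per-sample binary walking / non-walking stream (1 = walking)."""

    labels: np.ndarray
    fs: float

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 1:
            raise ParameterError(f"labels must be one-dimensional, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ParameterError("label series must contain at least one sample")
        if not np.isin(arr, (0, 1)).all():
            raise ParameterError("labels must contain only 0 and 1")
        if not float(self.fs) > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "labels", arr.astype(np.uint8))
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        return self.labels.shape[0]


#: bout classifications used throughout the pipeline
BOUT_KINDS = ("gap", "activity", "walking", "rejected_transition", "rejected_short")


@dataclass(frozen=True, order=True)
class Bout:
    """A half-open frame interval ``[start_frame, end_frame)`` with a kind."""

    start_frame: int
    end_frame: int
    kind: str = field(default="activity", compare=True)

    def __post_init__(self):
        if self.start_frame < 0 or self.end_frame <= self.start_frame:
            raise ParameterError(
                f"invalid bout [{self.start_frame}, {self.end_frame})"
            )
        if self.kind not in BOUT_KINDS:
            raise ParameterError(f"unknown bout kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration_s(self, fs: float) -> float:
        return self.n_frames / fs


@dataclass(frozen=True)
class BoutSet:
    """An ordered, pairwise-disjoint collection of bouts on one trace."""

    bouts: tuple
    n: int
    fs: float

    def __post_init__(self):
        bouts = tuple(self.bouts)
        prev_end = 0
        for b in bouts:
            if not isinstance(b, Bout):
                raise ParameterError("bouts must be Bout instances")
            if b.start_frame < prev_end:
                raise ParameterError("bouts must be sorted and pairwise disjoint")
            if b.end_frame > self.n:
                raise ParameterError(
                    f"bout [{b.start_frame}, {b.end_frame}) exceeds trace length {self.n}"
                )
            prev_end = b.end_frame
        if not float(self.fs) > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "bouts", bouts)
        object.__setattr__(self, "fs", float(self.fs))

    def __iter__(self) -> Iterator[Bout]:
        return iter(self.bouts)

    def __len__(self) -> int:
        return len(self.bouts)

    def of_kind(self, *kinds: str) -> "BoutSet":
        return BoutSet(tuple(b for b in self.bouts if b.kind in kinds), self.n, self.fs)

    @property
    def walking(self) -> "BoutSet":
        return self.of_kind("walking")

    def total_frames(self) -> int:
        return sum(b.n_frames for b in self.bouts)

    def to_labels(self, kinds: Sequence[str] = ("walking",)) -> LabelSeries:
        """Per-sample 0/1 series that is 1 inside bouts of the given kinds."""
        lab = np.zeros(self.n, dtype=np.uint8)
        for b in self.bouts:
            if b.kind in kinds:
                lab[b.start_frame : b.end_frame] = 1
        return LabelSeries(lab, self.fs)

    @classmethod
    def from_labels(cls, labels: LabelSeries, kind: str = "activity") -> "BoutSet":
        """Maximal runs of 1s as bouts of ``kind`` (inverse of to_labels)."""
        runs = _runs_of(labels.labels, 1)
        bouts = tuple(Bout(s, e, kind) for s, e in runs)
        return cls(bouts, labels.n, labels.fs)


def _runs_of(arr: np.ndarray, value: int) -> list:
    """Half-open [start, end) intervals of maximal runs equal to ``value``."""
    mask = np.asarray(arr) == value
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
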