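"""Per-sample scoring of detector output against ground-truth labels.

Predictions and truth are compared sample by sample: a true positive is a
sample both streams call walking, a true negative one both call
non-walking. Six metrics derive from the counts; metrics with a zero
denominator are carried as explicit NaN markers (never coerced to 0) and
skipped, with a recorded count, when averaging across participants. Each
participant contributes one report, so the cohort summary weights every
participant equally regardless of recording length.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .detector import DetectorConfig, detect
from .types import AccelTrace, AlignmentError, LabelSeries, ParameterError

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "CohortSummary",
    "confusion",
    "metrics",
    "cohort_average",
    "timing_per_block",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "npv", "accuracy", "f1")

#: explicit marker for a metric whose denominator is zero
UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return not math.isnan(x)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-sample confusion counts (prediction vs ground truth)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    """Six classification metrics plus the counts they derive from."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    f1: float
    participant_id: Optional[str] = None

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise ParameterError(f"unknown metric {name!r}")
        return getattr(self, name)


def confusion(pred: LabelSeries, truth: LabelSeries) -> ConfusionCounts:
    """Count per-sample agreement between prediction and ground truth."""
    if pred.n != truth.n:
        raise AlignmentError(
            f"prediction ({pred.n} samples) and truth ({truth.n} samples) differ in length"
        )
    if abs(pred.fs - truth.fs) > 1e-9:
        raise AlignmentError(
            f"prediction (fs={pred.fs}) and truth (fs={truth.fs}) differ in rate"
        )
    p = pred.labels.astype(bool)
    t = truth.labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def metrics(counts: ConfusionCounts, participant_id: Optional[str] = None) -> EvalReport:
    """Derive the six metrics from confusion counts.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    precision = tp/(tp+fp), npv = tn/(tn+fn),
    accuracy = (tp+tn)/total, f1 = harmonic mean of precision and
    sensitivity. Zero denominators yield NaN markers; an undefined
    precision or sensitivity propagates to an undefined F1.
    """
    if counts.total == 0:
        raise ParameterError("cannot compute metrics on an empty comparison")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    acc = (counts.tp + counts.tn) / counts.total
    if is_defined(prec) and is_defined(sens) and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = UNDEFINED
    return EvalReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        npv=npv,
        accuracy=acc,
        f1=f1,
        participant_id=participant_id,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Unweighted per-metric mean and s.d. across participants.

    ``n_defined`` and ``n_skipped`` record, per metric, how many reports
    contributed and how many were undefined (zero denominator) and skipped.
    The s.d. uses the n-1 denominator; with a single defined report it is
    the NaN marker.
    """

    mean: Dict[str, float]
    sd: Dict[str, float]
    n_defined: Dict[str, int]
    n_skipped: Dict[str, int]
    n_reports: int


def cohort_average(reports: Sequence[EvalReport]) -> CohortSummary:
    """Average metrics across participants with equal weight per report."""
    if len(reports) == 0:
        raise ParameterError("cohort_average requires at least one report")
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    n_defined: Dict[str, int] = {}
    n_skipped: Dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metric(name) for r in reports], dtype=np.float64)
        defined = vals[~np.isnan(vals)]
        n_defined[name] = int(defined.size)
        n_skipped[name] = int(vals.size - defined.size)
        mean[name] = float(defined.mean()) if defined.size else UNDEFINED
        sd[name] = float(defined.std(ddof=1)) if defined.size > 1 else UNDEFINED
    return CohortSummary(
        mean=mean, sd=sd, n_defined=n_defined, n_skipped=n_skipped,
        n_reports=len(reports),
    )


def timing_per_block(
    trace: AccelTrace, cfg: Optional[DetectorConfig] = None, repeats: int = 3
) -> float:
    """Wall-clock cost of ``detect`` in milliseconds per 6000 frames.

    6000 frames is 10 min of data at the nominal 100 Hz. Informational
    only: the figure depends on the host hardware.
    """
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    elapsed = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        detect(trace, cfg)
        elapsed.append(time.perf_counter() - t0)
    mean_s = sum(elapsed) / repeats
    return mean_s / trace.n * 6000.0 * 1000.0
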