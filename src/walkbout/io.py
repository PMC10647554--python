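"""Delimited-text readers and writers for traces, labels, bouts, reports.

All writers use a stable column order and fixed float formatting so that
two runs on identical inputs produce byte-identical files. Gzip-compressed
inputs are handled transparently (by extension).
"""

from __future__ import annotations

import gzip
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .evaluate import CohortSummary, EvalReport, METRIC_NAMES
from .personalize import PersonalThreshold
from .types import (
    AccelTrace,
    AlignmentError,
    Bout,
    BoutSet,
    LabelSeries,
    ParameterError,
)

__all__ = [
    "read_trace",
    "write_trace",
    "read_labels",
    "write_labels",
    "read_bouts",
    "write_bouts",
    "write_report",
    "read_calibration",
    "write_calibration",
    "load_config",
]

PathLike = Union[str, Path]

_AXIS_NAMES = ("ax", "ay", "az")
_TIME_NAMES = ("t", "time", "timestamp", "seconds")


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_header_fs(path: PathLike) -> Optional[float]:
    """Parse a leading ``# fs=100`` / ``# fs: 100`` comment, if present."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip().replace(":", "=")
            if body.lower().startswith("fs"):
                try:
                    return float(body.split("=", 1)[1])
                except (IndexError, ValueError):
                    raise ParameterError(f"unparseable fs header line: {line!r}")
    return None


def _sniff_table(path: PathLike, sep: Optional[str]) -> pd.DataFrame:
    """Read a delimited table, with or without a header row."""
    kwargs = dict(comment="#", engine="python") if sep is None else dict(comment="#")
    first = pd.read_csv(path, sep=sep, header=None, nrows=1, **kwargs)
    has_header = False
    for v in first.iloc[0]:
        try:
            float(v)
        except (TypeError, ValueError):
            has_header = True
            break
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, **kwargs)
    if has_header:
        df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _resolve_columns(df: pd.DataFrame) -> Tuple[Optional[str], Sequence[str]]:
    """Find the time column (if any) and the three axis columns."""
    cols = list(df.columns)
    named_axes = [c for c in cols if c in _AXIS_NAMES]
    if len(named_axes) == 3:
        time_col = next((c for c in cols if c in _TIME_NAMES), None)
        return time_col, _AXIS_NAMES
    if isinstance(cols[0], str) and any(c in _AXIS_NAMES for c in cols):
        missing = [c for c in _AXIS_NAMES if c not in cols]
        raise ParameterError(f"trace file is missing acceleration columns: {missing}")
    if len(cols) == 3:
        return None, cols
    if len(cols) >= 4:
        return cols[0], cols[1:4]
    raise ParameterError(
        f"trace file must have 3 acceleration columns (+ optional time), got {len(cols)}"
    )


def _fs_from_time(t: pd.Series) -> Tuple[float, Optional[object]]:
    if t.dtype == object or str(t.dtype).startswith("datetime"):
        try:
            ts = pd.to_datetime(t, format="ISO8601")
        except (ValueError, TypeError):
            raise ParameterError("time column is neither numeric nor ISO-8601")
        seconds = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
        t0 = str(ts.iloc[0])
    else:
        seconds = t.to_numpy(dtype=np.float64)
        t0 = float(seconds[0])
    dt = np.diff(seconds)
    if len(dt) == 0:
        raise ParameterError("cannot infer sampling rate from a single sample")
    med = float(np.median(dt))
    if med <= 0 or np.any(np.abs(dt - med) > 0.01 * med + 1e-9):
        raise ParameterError("inconsistent timestamps: sample spacing varies by > 1%")
    return 1.0 / med, t0


def _repair_nans(xyz: np.ndarray, fs: float) -> np.ndarray:
    """Linearly interpolate NaN gaps shorter than 1 s; error otherwise."""
    bad = ~np.isfinite(xyz).all(axis=1)
    if not bad.any():
        return xyz
    if bad[0] or bad[-1]:
        raise ParameterError("cannot repair missing samples at the trace boundary")
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    max_gap = int(math.ceil(fs))  # 1 s
    for run in splits:
        if len(run) >= max_gap:
            raise ParameterError(
                f"missing-data gap of {len(run) / fs:.2f} s at frame {run[0]} "
                "exceeds the repairable 1 s"
            )
    good = ~bad
    xs = np.flatnonzero(good)
    out = xyz.copy()
    for k in range(3):
        out[bad, k] = np.interp(np.flatnonzero(bad), xs, xyz[good, k])
    return out


def read_trace(
    path: PathLike,
    fs: Optional[float] = None,
    sep: Optional[str] = None,
    repair: bool = False,
) -> AccelTrace:
    """Read a delimited-text acceleration trace (units g).

    The sampling rate is taken, in order of precedence, from a ``# fs=...``
    header comment, from a time column (numeric seconds or ISO-8601
    clock times; spacing must be regular to 1%), or from the ``fs``
    argument. With ``repair=True``, missing samples in gaps shorter than
    1 s are linearly interpolated; longer gaps are an error.
    """
    header_fs = _read_header_fs(path)
    df = _sniff_table(path, sep)
    time_col, axis_cols = _resolve_columns(df)
    t0 = None
    inferred_fs = None
    if time_col is not None:
        inferred_fs, t0 = _fs_from_time(df[time_col])
    final_fs = header_fs or inferred_fs or fs
    if final_fs is None:
        raise ParameterError(
            "sampling rate unknown: provide a '# fs=' header, a time column, or fs="
        )
    try:
        xyz = df[list(axis_cols)].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as err:
        raise ParameterError(f"non-numeric acceleration value: {err}") from err
    bad = ~np.isfinite(xyz).all(axis=1)
    if bad.any():
        if repair:
            xyz = _repair_nans(xyz, final_fs)
        else:
            raise ParameterError(
                f"non-finite acceleration value at data row {int(np.flatnonzero(bad)[0])}"
            )
    return AccelTrace(xyz, final_fs, t0)


def write_trace(trace: AccelTrace, path: PathLike) -> None:
    """Write a trace as ``t,ax,ay,az`` CSV with an ``# fs=`` header."""
    path = Path(path)
    t = np.arange(trace.n) / trace.fs
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={trace.fs:g}\n")
        fh.write("t,ax,ay,az\n")
        for i in range(trace.n):
            fh.write(
                f"{t[i]:.4f},{trace.xyz[i, 0]:.6f},"
                f"{trace.xyz[i, 1]:.6f},{trace.xyz[i, 2]:.6f}\n"
            )


def read_labels(path: PathLike, fs: Optional[float] = None) -> LabelSeries:
    """Read a per-sample 0/1 label stream (one column, header optional)."""
    header_fs = _read_header_fs(path)
    df = _sniff_table(path, sep=",")  # single column: nothing to sniff
    col = "label" if "label" in df.columns else df.columns[-1]
    vals = df[col].to_numpy()
    uniq = np.unique(vals)
    if not np.isin(uniq, (0, 1)).all():
        raise ParameterError(f"labels must be 0 or 1, found values {uniq.tolist()[:5]}")
    final_fs = header_fs or fs
    if final_fs is None:
        raise ParameterError("sampling rate unknown: provide a '# fs=' header or fs=")
    return LabelSeries(vals.astype(np.uint8), final_fs)


def write_labels(labels: LabelSeries, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={labels.fs:g}\n")
        fh.write("label\n")
        fh.write("\n".join(str(int(v)) for v in labels.labels))
        fh.write("\n")


_BOUT_COLUMNS = "participant_id,start_frame,end_frame,start_time_s,duration_s,kind"


def write_bouts(bouts: BoutSet, path: PathLike, participant_id: str = "") -> None:
    """Write a bout table; metadata header keeps the round trip lossless."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# n={bouts.n} fs={bouts.fs:g}\n")
        fh.write(_BOUT_COLUMNS + "\n")
        for b in bouts:
            fh.write(
                f"{participant_id},{b.start_frame},{b.end_frame},"
                f"{b.start_frame / bouts.fs:.3f},{b.duration_s(bouts.fs):.3f},{b.kind}\n"
            )


def read_bouts(path: PathLike) -> BoutSet:
    with _open_text(path) as fh:
        meta = fh.readline().strip()
    if not meta.startswith("#"):
        raise ParameterError("bout file is missing its '# n=... fs=...' metadata line")
    fields = dict(kv.split("=") for kv in meta.lstrip("#").split())
    n, fs = int(fields["n"]), float(fields["fs"])
    df = pd.read_csv(path, comment="#", header=0)
    if len(df) == 0:
        return BoutSet((), n, fs)
    bouts = tuple(
        Bout(int(r.start_frame), int(r.end_frame), str(r.kind))
        for r in df.itertuples()
    )
    return BoutSet(bouts, n, fs)


def write_report(
    report: Union[EvalReport, CohortSummary], path: PathLike
) -> None:
    """Write a per-participant report or cohort summary as CSV.

    Undefined metrics are written as the literal ``undefined``.
    """

    def fmt(x: float) -> str:
        return "undefined" if (isinstance(x, float) and math.isnan(x)) else f"{x:.6f}"

    with open(path, "w", newline="") as fh:
        if isinstance(report, EvalReport):
            fh.write("metric,value\n")
            c = report.counts
            for name in METRIC_NAMES:
                fh.write(f"{name},{fmt(report.metric(name))}\n")
            fh.write(f"tp,{c.tp}\nfp,{c.fp}\nfn,{c.fn}\ntn,{c.tn}\n")
        else:
            fh.write("metric,mean,sd,n_defined,n_skipped\n")
            for name in METRIC_NAMES:
                fh.write(
                    f"{name},{fmt(report.mean[name])},{fmt(report.sd[name])},"
                    f"{report.n_defined[name]},{report.n_skipped[name]}\n"
                )


def write_calibration(
    cal: PersonalThreshold, path: PathLike, min_gap_frames: int = 100
) -> None:
    record = {
        "value_g": cal.value_g,
        "source_window_hours": list(cal.source_window),
        "n_samples_used": cal.n_samples_used,
        "min_gap_frames": min_gap_frames,
        "mode": "personalized",
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibration(path: PathLike) -> Tuple[PersonalThreshold, int]:
    with open(path) as fh:
        record = json.load(fh)
    cal = PersonalThreshold(
        value_g=float(record["value_g"]),
        source_window=tuple(record["source_window_hours"]),
        n_samples_used=int(record["n_samples_used"]),
    )
    return cal, int(record.get("min_gap_frames", 100))


def load_config(path: PathLike) -> dict:
    """Load a YAML key/value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParameterError("config file must contain a key/value mapping")
    return cfg
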