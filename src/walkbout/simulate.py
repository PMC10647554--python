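"""Labeled synthetic lower-back accelerometer traces.

The generator emulates what the detector actually consumes: a gravity
baseline with sensor noise, quasi-periodic walking bursts whose magnitude
envelope crosses the activity threshold, and high-amplitude sit-stand
transients. Walking is a two-harmonic sinusoid with phase jitter rather
than a biomechanical gait model: the detector exploits only the magnitude
envelope, never waveform shape. A whole-trace rotation emulates arbitrary
fixed sensor orientation, and per-sample truth labels (1 exactly on walk
segments) make every stage testable without a real recording.

All randomness flows from one explicitly seeded generator per scenario;
identical (spec, seed) gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import AccelTrace, LabelSeries, ParameterError

__all__ = [
    "Segment",
    "ScenarioSpec",
    "LabeledTrace",
    "gen_stationary",
    "gen_walk",
    "gen_transition",
    "build_scenario",
    "corridor_protocol",
    "calibration_day",
    "stationary_day",
    "slow_gait_scenario",
    "halting_gait_scenario",
    "shuffling_scenario",
    "transition_scenario",
    "Participant",
    "make_cohort",
    "build_calibration_day",
]

DEFAULT_FS = 100.0
#: per-axis white-noise s.d. of a quiet seated rest, in g
DEFAULT_REST_SIGMA_G = 0.012


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ParameterError("direction vector must be nonzero")
    return v / norm


def _n_frames(duration_s: float, fs: float) -> int:
    if not duration_s > 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    return max(1, int(round(duration_s * fs)))


@dataclass(frozen=True)
class Segment:
    """One building block of a scenario: kind, duration, parameters."""

    kind: str
    duration_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("stationary", "walk", "transition"):
            raise ParameterError(f"unknown segment kind {self.kind!r}")
        if not self.duration_s > 0:
            raise ParameterError(f"duration_s must be > 0, got {self.duration_s}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A full synthetic recording: ordered segments, orientation, noise, seed."""

    segments: Tuple[Segment, ...]
    fs: float = DEFAULT_FS
    orientation: Optional[object] = None  # 3x3 matrix or 3 Euler angles (rad)
    noise_sigma_g: float = DEFAULT_REST_SIGMA_G
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise ParameterError("scenario needs at least one segment")
        if not self.fs > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if self.noise_sigma_g < 0:
            raise ParameterError("noise_sigma_g must be >= 0")


@dataclass(frozen=True)
class LabeledTrace:
    """A synthetic trace with per-sample truth and its segment table."""

    trace: AccelTrace
    truth: LabelSeries
    segment_table: Tuple[Tuple[str, int, int], ...]


def resolve_rotation(orientation) -> np.ndarray:
    """Turn an orientation spec (None, 3x3 matrix, or Euler xyz radians)
    into a validated proper rotation matrix."""
    if orientation is None:
        return np.eye(3)
    arr = np.asarray(orientation, dtype=np.float64)
    if arr.shape == (3,):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", arr).as_matrix()
    elif arr.shape == (3, 3):
        R = arr
    else:
        raise ParameterError(
            f"orientation must be a 3x3 matrix or 3 Euler angles, got shape {arr.shape}"
        )
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-9
    ):
        raise ParameterError("orientation must be a proper orthonormal rotation")
    return R


# ---------------------------------------------------------------------------
# segment generators (clean signal incl. gravity; noise is added on top by
# build_scenario, with a per-segment override of the scenario sigma)
# ---------------------------------------------------------------------------

def gen_stationary(
    duration_s: float,
    fs: float = DEFAULT_FS,
    noise_sigma_g: float = 0.0,
    gravity_dir=(0.0, 0.0, 1.0),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Gravity (1 g along ``gravity_dir``) plus optional i.i.d. noise."""
    if noise_sigma_g < 0:
        raise ParameterError("noise_sigma_g must be >= 0")
    n = _n_frames(duration_s, fs)
    xyz = np.tile(_unit(gravity_dir), (n, 1))
    if noise_sigma_g > 0:
        rng = rng or np.random.default_rng()
        xyz = xyz + rng.normal(0.0, noise_sigma_g, size=(n, 3))
    return xyz


def gen_walk(
    duration_s: float,
    fs: float = DEFAULT_FS,
    step_hz: float = 1.8,
    amp_g: float = 0.2,
    harmonic_ratio: float = 0.35,
    lateral_ratio: float = 0.25,
    phase_jitter: float = 0.03,
    ramp_s: float = 0.5,
    pauses: Optional[Sequence[Tuple[float, float]]] = None,
    gravity_dir=(0.0, 0.0, 1.0),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Quasi-periodic walking burst superposed on gravity.

    Fundamental at ``step_hz`` on the anterior-posterior axis, a harmonic
    at twice the step frequency on the vertical axis, and lateral sway;
    per-sample phase jitter breaks strict periodicity. The amplitude ramps
    over ``ramp_s`` at both ends, and optional ``pauses`` — (start_s,
    duration_s) relative to segment start — gate the envelope to zero to
    mimic halting gait.
    """
    if not 0.3 <= step_hz <= 3.5:
        raise ParameterError(f"step_hz must be within [0.3, 3.5], got {step_hz}")
    if not amp_g > 0:
        raise ParameterError(f"amp_g must be > 0, got {amp_g}")
    n = _n_frames(duration_s, fs)
    base_inc = 2.0 * np.pi * step_hz / fs
    if rng is not None and phase_jitter > 0:
        inc = base_inc * (1.0 + rng.normal(0.0, phase_jitter, size=n))
    else:
        inc = np.full(n, base_inc)
    phase = np.cumsum(inc)

    env = np.ones(n)
    ramp_n = min(_n_frames(max(ramp_s, 1.0 / fs), fs), n // 2)
    if ramp_s > 0 and ramp_n > 1:
        ramp = np.linspace(0.0, 1.0, ramp_n)
        env[:ramp_n] *= ramp
        env[-ramp_n:] *= ramp[::-1]
    if pauses:
        taper_n = max(1, int(round(0.2 * fs)))
        for start_s, dur_s in pauses:
            s = int(round(start_s * fs))
            e = int(round((start_s + dur_s) * fs))
            if not (0 <= s < e <= n):
                raise ParameterError(
                    f"pause ({start_s}, {dur_s}) outside the walk segment"
                )
            env[s:e] = 0.0
            lo = max(0, s - taper_n)
            env[lo:s] *= np.linspace(1.0, 0.0, s - lo, endpoint=False)
            hi = min(n, e + taper_n)
            env[e:hi] *= np.linspace(0.0, 1.0, hi - e, endpoint=False)

    g = _unit(gravity_dir)
    # anterior-posterior axis: any unit vector orthogonal to gravity
    ap = np.array([1.0, 0.0, 0.0])
    if abs(ap @ g) > 0.9:
        ap = np.array([0.0, 1.0, 0.0])
    ap = _unit(ap - (ap @ g) * g)
    lat = np.cross(g, ap)

    motion = (
        np.outer(env * amp_g * np.sin(phase), ap)
        + np.outer(env * harmonic_ratio * amp_g * np.sin(2.0 * phase + 0.7), g)
        + np.outer(env * lateral_ratio * amp_g * np.sin(phase + np.pi / 2), lat)
    )
    return np.tile(g, (n, 1)) + motion


def _tapered_lobe(n: int, taper: float = 0.3) -> np.ndarray:
    """A flat-topped (tapered-square) unit lobe of n samples."""
    t = np.arange(n) / max(n - 1, 1)
    lobe = np.ones(n)
    r = taper / 2.0
    rising = t < r
    lobe[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / r))
    falling = t > 1.0 - r
    lobe[falling] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - t[falling]) / r))
    return lobe


def gen_transition(
    duration_s: float = 1.5,
    fs: float = DEFAULT_FS,
    peak_g: float = 0.8,
    gravity_dir=(0.0, 0.0, 1.0),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Oscillatory sit-stand transient on the vertical axis.

    The trunk accelerates upward, brakes, and settles: four flat-topped
    lobes of alternating sign (amplitudes 1, -1, 0.7, -0.7 relative to
    ``peak_g``). Opposite lobes cancel pairwise, so velocity returns to
    rest and the transient carries almost no content below the 0.25 Hz
    detrending cut-off — detrending leaves it intact without ringing into
    the neighbouring rest. No periodicity beyond the single event.
    """
    if not peak_g >= 0:
        raise ParameterError(f"peak_g must be >= 0, got {peak_g}")
    n = _n_frames(duration_s, fs)
    amps = (1.0, -1.0, 0.7, -0.7)
    bounds = np.linspace(0, n, len(amps) + 1).astype(int)
    shape = np.zeros(n)
    prev_area = 0.0
    for amp, lo, hi in zip(amps, bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        lobe = amp * _tapered_lobe(hi - lo)
        if amp < 0 and lobe.sum() != 0:
            lobe *= prev_area / -lobe.sum()  # brake exactly cancels the push
        else:
            prev_area = lobe.sum()
        shape[lo:hi] = lobe
    g = _unit(gravity_dir)
    return np.tile(g, (n, 1)) + np.outer(peak_g * shape, g)


_GENERATORS = {
    "stationary": gen_stationary,
    "walk": gen_walk,
    "transition": gen_transition,
}


def build_scenario(spec: ScenarioSpec) -> LabeledTrace:
    """Concatenate segments, rotate, add noise, and emit truth labels."""
    R = resolve_rotation(spec.orientation)
    rng = np.random.default_rng(spec.seed)
    parts: List[np.ndarray] = []
    table: List[Tuple[str, int, int]] = []
    sigmas: List[np.ndarray] = []
    cursor = 0
    for seg in spec.segments:
        params = dict(seg.params)
        sigma = float(params.pop("noise_sigma_g", spec.noise_sigma_g))
        if sigma < 0:
            raise ParameterError("noise_sigma_g must be >= 0")
        gen = _GENERATORS[seg.kind]
        xyz = gen(seg.duration_s, fs=spec.fs, rng=rng, **params)
        parts.append(xyz)
        sigmas.append(np.full(xyz.shape[0], sigma))
        table.append((seg.kind, cursor, cursor + xyz.shape[0]))
        cursor += xyz.shape[0]
    xyz = np.concatenate(parts, axis=0)
    sigma_per_sample = np.concatenate(sigmas)
    noise = rng.standard_normal(xyz.shape) * sigma_per_sample[:, None]
    # noise is added in the body frame and rotated with the signal, so a
    # scenario with an orientation is exactly a rotation of the same trace
    trace = AccelTrace((xyz + noise) @ R.T, spec.fs)
    truth = np.zeros(trace.n, dtype=np.uint8)
    for kind, s, e in table:
        if kind == "walk":
            truth[s:e] = 1
    return LabeledTrace(
        trace=trace,
        truth=LabelSeries(truth, spec.fs),
        segment_table=tuple(table),
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def corridor_protocol(
    step_hz: float = 1.8,
    amp_g: float = 0.2,
    transition_peak_g: float = 0.8,
    transition_s: float = 1.2,
    walk_s: float = 45.0,
    settle_s: float = 3.0,
    rest_sigma_g: float = DEFAULT_REST_SIGMA_G,
    fs: float = DEFAULT_FS,
    orientation=None,
    seed: int = 0,
) -> ScenarioSpec:
    """The in-home validation walk: sit, stand, walk a corridor, sit, rest,
    stand, walk back, sit.

    A short ``settle_s`` stationary interval separates each sit-stand
    transient from the adjacent walk — the wearer steadies before stepping
    off — so the high-acceleration transient forms its own activity bout.
    Exactly two walking segments carry truth label 1.
    """
    sit = lambda d: Segment("stationary", d, {"noise_sigma_g": rest_sigma_g})
    trans = Segment(
        "transition", transition_s, {"peak_g": transition_peak_g, "noise_sigma_g": rest_sigma_g}
    )
    walk = Segment(
        "walk", walk_s,
        {"step_hz": step_hz, "amp_g": amp_g, "noise_sigma_g": rest_sigma_g},
    )
    segments = (
        sit(60.0), trans, sit(settle_s), walk, sit(settle_s), trans,
        sit(24.0), trans,
        sit(settle_s), walk, sit(settle_s), trans, sit(60.0),
    )
    return ScenarioSpec(
        segments=segments, fs=fs, orientation=orientation,
        noise_sigma_g=rest_sigma_g, seed=seed,
    )


def stationary_day(
    sigma_g: float,
    hours: float = 24.0,
    activity_fraction: float = 0.04,
    walk_amp_g: float = 0.15,
    step_hz: float = 1.6,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> ScenarioSpec:
    """A calibration day that is almost entirely stationary noise.

    ``activity_fraction`` of the duration is spread over four walking
    bursts. With at most ~5% activity the median detrended magnitude is
    the median of the stationary noise magnitude — chi-distributed with
    3 degrees of freedom, median ``sigma * 1.5382``.
    """
    if not 0 <= activity_fraction < 0.5:
        raise ParameterError("activity_fraction must be in [0, 0.5)")
    total_s = hours * 3600.0
    n_bursts = 4
    walk_each = activity_fraction * total_s / n_bursts
    quiet_each = (1 - activity_fraction) * total_s / (n_bursts + 1)
    segments: List[Segment] = [Segment("stationary", quiet_each, {"noise_sigma_g": sigma_g})]
    for _ in range(n_bursts):
        if walk_each > 0:
            segments.append(
                Segment("walk", walk_each,
                        {"step_hz": step_hz, "amp_g": walk_amp_g, "noise_sigma_g": sigma_g})
            )
        segments.append(Segment("stationary", quiet_each, {"noise_sigma_g": sigma_g}))
    return ScenarioSpec(segments=tuple(segments), fs=fs, noise_sigma_g=sigma_g, seed=seed)


def calibration_day(
    active_sigma_g: float = 0.06,
    sleep_sigma_g: float = 0.004,
    quiet_sigma_g: float = DEFAULT_REST_SIGMA_G,
    hours: float = 24.0,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> ScenarioSpec:
    """A realistic free-living calibration day.

    Sleep (~7 h of near-silent lying) and quiet sitting (~1 h) are the only
    truly still periods; the ~16 waking hours carry sustained low-grade
    ambient movement (posture shifts, fidgeting, handling — modelled as
    per-axis noise of ``active_sigma_g``) interleaved with short walks and
    sit-stand transients. Because most of the day is spent in this ambient
    band, the 24-h median lands inside it, above the quiet-rest noise floor
    — the property that makes the personalized threshold conservative
    relative to the generic 0.05 g.
    """
    scale = hours / 24.0
    sleep = Segment("stationary", 7 * 3600 * scale, {"noise_sigma_g": sleep_sigma_g})
    quiet = Segment("stationary", 1 * 3600 * scale, {"noise_sigma_g": quiet_sigma_g})
    segments: List[Segment] = [sleep, quiet]
    n_blocks = 16
    block_s = 3600 * scale
    for _ in range(n_blocks):
        walk_s = 90.0 * scale
        trans_s = 1.2
        active_s = block_s - walk_s - 2 * trans_s
        segments.extend(
            [
                Segment("transition", trans_s,
                        {"peak_g": 0.7, "noise_sigma_g": active_sigma_g}),
                Segment("stationary", active_s * 0.6, {"noise_sigma_g": active_sigma_g}),
                Segment("walk", walk_s,
                        {"step_hz": 1.5, "amp_g": 0.15, "noise_sigma_g": active_sigma_g}),
                Segment("stationary", active_s * 0.4, {"noise_sigma_g": active_sigma_g}),
                Segment("transition", trans_s,
                        {"peak_g": 0.7, "noise_sigma_g": active_sigma_g}),
            ]
        )
    return ScenarioSpec(segments=tuple(segments), fs=fs, noise_sigma_g=quiet_sigma_g, seed=seed)


def slow_gait_scenario(seed: int = 0, fs: float = DEFAULT_FS) -> ScenarioSpec:
    """Very slow gait (0.9 Hz step) between rests — a frail-walker profile."""
    return ScenarioSpec(
        segments=(
            Segment("stationary", 40.0),
            Segment("walk", 30.0, {"step_hz": 0.9, "amp_g": 0.12}),
            Segment("stationary", 40.0),
        ),
        fs=fs, seed=seed,
    )


def halting_gait_scenario(
    seed: int = 0, pause_s: float = 3.0, fs: float = DEFAULT_FS
) -> ScenarioSpec:
    """Walking interrupted by a full stop mid-bout (halting gait)."""
    return ScenarioSpec(
        segments=(
            Segment("stationary", 40.0),
            Segment(
                "walk", 30.0,
                {"step_hz": 1.4, "amp_g": 0.15, "pauses": ((13.0, pause_s),)},
            ),
            Segment("stationary", 40.0),
        ),
        fs=fs, seed=seed,
    )


def shuffling_scenario(seed: int = 0, fs: float = DEFAULT_FS) -> ScenarioSpec:
    """Sub-threshold shuffling: movement too weak to cross 0.05 g."""
    return ScenarioSpec(
        segments=(
            Segment("stationary", 40.0),
            Segment("walk", 30.0, {"step_hz": 1.0, "amp_g": 0.02}),
            Segment("stationary", 40.0),
        ),
        fs=fs, noise_sigma_g=0.005, seed=seed,
    )


def transition_scenario(
    peak_g: float = 0.8,
    duration_s: float = 1.2,
    seed: int = 0,
    fs: float = DEFAULT_FS,
) -> ScenarioSpec:
    """An isolated sit-stand transient between long rests."""
    return ScenarioSpec(
        segments=(
            Segment("stationary", 30.0),
            Segment("transition", duration_s, {"peak_g": peak_g}),
            Segment("stationary", 30.0),
        ),
        fs=fs, seed=seed,
    )


# ---------------------------------------------------------------------------
# the scaled-down validation cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Participant:
    """One synthetic participant: their corridor recording and the
    parameters needed to rebuild their free-living calibration day."""

    participant_id: str
    corridor: LabeledTrace
    day_seed: int
    day_active_sigma_g: float


def make_cohort(
    n_participants: int = 10, seed: int = 0, fs: float = DEFAULT_FS
) -> List[Participant]:
    """A synthetic validation cohort walking the corridor protocol.

    Gait cadence spans slow to brisk (0.8-2.2 Hz), burst amplitude
    0.13-0.30 g, sit-stand peaks 0.6-1.0 g — a clean-gait analog of a
    frail-resident protocol, one recording per participant.
    """
    base = np.random.default_rng(seed)
    cohort: List[Participant] = []
    for i in range(n_participants):
        step_hz = float(base.uniform(0.8, 2.2))
        amp_g = float(base.uniform(0.13, 0.30))
        peak_g = float(base.uniform(0.6, 1.0))
        active_sigma = float(base.uniform(0.055, 0.07))
        scen_seed = int(base.integers(0, 2**31 - 1))
        day_seed = int(base.integers(0, 2**31 - 1))
        spec = corridor_protocol(
            step_hz=step_hz, amp_g=amp_g, transition_peak_g=peak_g,
            fs=fs, seed=scen_seed,
        )
        cohort.append(
            Participant(
                participant_id=f"P{i + 1:02d}",
                corridor=build_scenario(spec),
                day_seed=day_seed,
                day_active_sigma_g=active_sigma,
            )
        )
    return cohort


def build_calibration_day(
    participant: Participant, hours: float = 24.0, fs: float = DEFAULT_FS
) -> AccelTrace:
    """Rebuild a participant's free-living calibration day on demand."""
    spec = calibration_day(
        active_sigma_g=participant.day_active_sigma_g,
        hours=hours, fs=fs, seed=participant.day_seed,
    )
    return build_scenario(spec).trace
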