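"""Signal conditioning: gravity removal, 3D norm, Gaussian smoothing.

The detector never looks at individual axes after this stage. Gravity and
slow postural drift are estimated per axis with a 4th-order zero-phase
low-pass Butterworth filter (cut-off 0.25 Hz) and subtracted, centring the
movement content around 0 g; the Euclidean norm of the three detrended axes
then yields a single orientation-independent activity magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .types import (
    AccelTrace,
    ActivitySignal,
    ParameterError,
    TraceTooShortError,
)

__all__ = [
    "detrend",
    "magnitude",
    "SmoothingKernel",
    "gaussian_kernel",
    "default_kernel",
    "gaussian_smooth",
]

#: nominal sampling rate (Hz) at which frame-count thresholds are defined
NOMINAL_FS = 100.0


def detrend(trace: AccelTrace, cutoff_hz: float = 0.25, order: int = 4) -> AccelTrace:
    """Subtract the zero-phase low-pass estimate from each axis.

    The low-pass output tracks gravity plus posture; subtracting it leaves
    the movement band centred around 0 g while preserving all frequency
    content above ``cutoff_hz``. Zero phase is obtained by forward-backward
    application with odd reflection padding of three filter time constants
    (``3 * fs / cutoff_hz`` samples): a 0.25 Hz filter has a multi-second
    impulse response, so shorter pads would leave edge transients bleeding
    seconds into the signal. The filter runs as second-order sections
    (:func:`scipy.signal.sosfiltfilt`), which stays numerically exact at
    the very low normalized cut-off this detrending uses.

    Raises
    ------
    ParameterError
        If ``cutoff_hz`` is not strictly between 0 and the Nyquist rate.
    TraceTooShortError
        If the trace is shorter than three pad lengths, where the
        forward-backward filter is not reliable.
    """
    nyquist = trace.fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff_hz must be in (0, {nyquist}) for fs={trace.fs}, got {cutoff_hz}"
        )
    if order < 1:
        raise ParameterError(f"filter order must be >= 1, got {order}")
    sos = sps.butter(order, cutoff_hz / nyquist, btype="low", output="sos")
    padlen = int(round(3 * trace.fs / cutoff_hz))
    if trace.n <= 3 * padlen:
        raise TraceTooShortError(
            f"trace too short for zero-phase detrending: n={trace.n}, "
            f"need > {3 * padlen} samples"
        )
    baseline = sps.sosfiltfilt(sos, trace.xyz, axis=0, padlen=padlen)
    return replace(trace, xyz=trace.xyz - baseline)


def magnitude(trace: AccelTrace) -> ActivitySignal:
    """Euclidean norm of the three axes per sample (the 3D magnitude).

    Rotation-invariant: any fixed re-orientation of the sensor leaves the
    output unchanged up to floating-point rounding.
    """
    return ActivitySignal(np.linalg.norm(trace.xyz, axis=1), trace.fs)


@dataclass(frozen=True)
class SmoothingKernel:
    """Symmetric Gaussian moving-average weights.

    ``window_samples`` must be odd so the kernel is centred; weights sum to
    one, giving equal influence to past and future samples with closer
    samples weighted more.
    """

    window_samples: int
    sigma_samples: float
    weights: np.ndarray

    def __post_init__(self):
        if self.window_samples < 1 or self.window_samples % 2 == 0:
            raise ParameterError(
                f"window_samples must be odd and positive, got {self.window_samples}"
            )
        if not self.sigma_samples > 0:
            raise ParameterError(f"sigma_samples must be > 0, got {self.sigma_samples}")
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.window_samples,):
            raise ParameterError("weights length must equal window_samples")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("weights must sum to 1")
        if not np.allclose(w, w[::-1], atol=1e-12):
            raise ParameterError("weights must be symmetric about the centre")
        object.__setattr__(self, "weights", w)


def gaussian_kernel(window_samples: int, sigma_samples: float) -> SmoothingKernel:
    """Build a normalized Gaussian kernel of odd length."""
    if window_samples < 1 or window_samples % 2 == 0:
        raise ParameterError(
            f"window_samples must be odd and positive, got {window_samples}"
        )
    if not sigma_samples > 0:
        raise ParameterError(f"sigma_samples must be > 0, got {sigma_samples}")
    w = sps.windows.gaussian(window_samples, std=sigma_samples)
    return SmoothingKernel(window_samples, float(sigma_samples), w / w.sum())


def default_kernel(
    fs: float, window_s: float = 2.0, sigma_divisor: float = 5.0
) -> SmoothingKernel:
    """Default activity-likelihood kernel: a 2 s window, sigma = window / 5.

    The window spans the short dips below the activity threshold that the
    likelihood is meant to bridge, matching the 2 s minimum-bout scale; at
    the nominal 100 Hz this gives 201 samples with sigma 40.2.
    """
    if not window_s > 0:
        raise ParameterError(f"window_s must be > 0, got {window_s}")
    if not sigma_divisor > 0:
        raise ParameterError(f"sigma_divisor must be > 0, got {sigma_divisor}")
    n = int(round(window_s * fs))
    if n % 2 == 0:
        n += 1
    n = max(n, 3)
    return gaussian_kernel(n, n / sigma_divisor)


def gaussian_smooth(signal: ActivitySignal, kernel: SmoothingKernel) -> ActivitySignal:
    """Gaussian-weighted moving average with renormalized edges.

    Near the boundaries the kernel is truncated and its remaining weights
    renormalized, so a stationary edge is not dragged toward zero and the
    output has the same length as the input. The output of smoothing a
    binary series is the "activity likelihood", valued in [0, 1].
    """
    if kernel.window_samples > signal.n:
        raise ParameterError(
            f"kernel window ({kernel.window_samples}) longer than signal ({signal.n})"
        )
    num = np.convolve(signal.values, kernel.weights, mode="same")
    den = np.convolve(np.ones(signal.n), kernel.weights, mode="same")
    return ActivitySignal(num / den, signal.fs)


def scale_frames(frames_at_nominal: int, fs: float) -> int:
    """Rescale a frame-count threshold defined at the nominal 100 Hz."""
    return max(1, int(round(frames_at_nominal * fs / NOMINAL_FS)))
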