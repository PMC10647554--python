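"""A deliberately naive, straight-line reimplementation of the staged
classification, written independently of the vectorized pipeline.

Used only as a cross-check oracle in tests: plain Python loops, no numpy
beyond reading values out of the preprocessed signals.
"""

from walkbout import preprocess
from walkbout.types import ActivitySignal


def oracle_walking_bouts(trace, cfg, kernel=None):
    """Return the [start, end) walking bouts by brute force."""
    kernel = kernel or preprocess.default_kernel(trace.fs)
    detrended = preprocess.detrend(trace)
    mag = preprocess.magnitude(detrended)
    binary = [1 if v > cfg.activity_threshold_g else 0 for v in mag.values]
    lik = preprocess.gaussian_smooth(
        ActivitySignal([float(b) for b in binary], trace.fs), kernel
    ).values
    smoothed = preprocess.gaussian_smooth(mag, kernel).values
    n = len(binary)
    fs = trace.fs

    gaps = []
    i = 0
    while i < n:
        if binary[i] == 0:
            j = i
            while j < n and binary[j] == 0:
                j += 1
            gaps.append((i, j))
            i = j
        else:
            i += 1

    min_gap = max(1, round(cfg.min_gap_frames * fs / 100.0))
    retained = []
    for s, e in gaps:
        boundary = s == 0 or e == n
        count = 0
        for k in range(s, e):
            if lik[k] < cfg.likelihood_threshold:
                count += 1
        if boundary or count >= min_gap:
            retained.append((s, e))

    activity = []
    prev = 0
    for s, e in retained:
        if s > prev:
            activity.append((prev, s))
        prev = e
    if prev < n:
        activity.append((prev, n))

    walking = []
    for s, e in activity:
        above = 0
        for k in range(s, e):
            if smoothed[k] > cfg.heuristic_threshold_g:
                above += 1
        if above / (e - s) < cfg.heuristic_fraction and (e - s) / fs >= cfg.min_bout_seconds:
            walking.append((s, e))
    return walking
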