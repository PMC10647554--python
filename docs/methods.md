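# Methods

## Model and assumptions

`walkbout` classifies each sample of a lower-back triaxial accelerometer
trace as walking or non-walking using only the *magnitude envelope* of the
movement content. The underlying assumptions are:

* gravity and posture occupy the band below ~0.25 Hz and can be removed
  per axis by subtracting a zero-phase low-pass estimate;
* any activity raises the detrended 3D norm above a small threshold
  (0.05 g generically), while quiet rest does not;
* walking is *sustained* above-threshold activity (≥ 2 s) whose intensity
  stays moderate, whereas sit-stand transitions are brief events with
  high-acceleration content (> 0.4 g);
* the 3D norm makes the decision independent of sensor orientation, so a
  sensor glued on slightly rotated, or re-attached differently, changes
  nothing.

The staged procedure (binarize → likelihood smoothing → gap filtering →
transition rejection → minimum duration) is described operationally in the
README; every stage is a pure function of its inputs and the whole
pipeline is deterministic.

### Personalized calibration

The personalized variant replaces the population threshold with the median
of the detrended 3D magnitude over a ~24-h free-living day, on the
rationale that a wearer is stationary more often than moving, so the
median sits at their personal no-movement baseline. Two design choices
deserve emphasis:

* **The median is taken on the detrended magnitude**, because that is the
  signal the threshold is compared against downstream. A raw-magnitude
  median would sit near 1 g (gravity) and be useless.
* **Day boundaries are wear-time relative** (hours since recording start),
  not calendar midnight; `choose_calibration_day(week, 2)` extracts the
  third day of wear, by which time a wearer has acclimated to the sensor.

Calibration enforces a plausibility band (0, 0.5) g and a minimum window
of 20 h (tolerating minor loss within a day); `min_hours` may be lowered
deliberately for scaled-down experiments, since the median of a
stationary-dominated trace has the same distribution regardless of
duration. A failed calibration either raises or — with `fallback=True` —
warns and returns the generic configuration, so bad calibration data can
never silently change detection semantics.

When the wearer's free-living median exceeds 0.05 g (the typical case for
day-long wear that is mostly low-grade movement rather than machine-still
rest), the personalized variant is *more conservative* than the generic
one: it concedes a little sensitivity at bout edges and gains specificity.
The minimum gap threshold rises from 50 to 100 frames in this variant so
that the stricter threshold does not fragment genuine bouts.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `activity_threshold_g` | 0.05 (generic) / 24-h median (personalized) | g | minimum detrended 3D magnitude of any activity |
| `likelihood_threshold` | 0.2 | – | below this, a smoothed-binary sample counts as inactive |
| `min_gap_frames` | 50 generic / 100 personalized | frames @100 Hz | low-likelihood samples a gap needs to be kept as non-activity |
| `heuristic_threshold_g` | 0.4 | g | smoothed-magnitude level marking high-intensity content |
| `heuristic_fraction` | 0.025 | – | bout fraction above 0.4 g at which a bout stops being walking |
| `min_bout_seconds` | 2.0 | s | shortest admissible walking bout |
| `cutoff_hz`, `filter_order` | 0.25, 4 | Hz, – | detrending low-pass |
| `smooth_window_s`, `smooth_sigma_divisor` | 2.0, 5.0 | s, – | Gaussian kernel span and window/σ ratio |

Frame-count parameters are defined at the nominal 100 Hz and rescaled by
`fs/100` (rounded) for other rates; the kernel is defined in seconds and
scales naturally.

**Gaussian kernel choice.** The smoothing kernel is not uniquely dictated
by the algorithm's description, so its parameters are this package's own
choice, exposed in configuration: a 2 s window (201 samples at 100 Hz,
forced odd so the kernel is centred and phase-free) with σ = window/5.
The window must span the short threshold dips the likelihood is meant to
bridge, and 2 s matches the minimum-bout scale; σ = window/5 keeps ~99% of
the Gaussian mass inside the window. The same kernel smooths both the
binary series (→ likelihood) and the magnitude (→ transition heuristic):
only one smoothing filter exists in the design.

**Tie-breaking** is uniformly conservative toward non-walking: binarize
uses strict `>` (a sample exactly at threshold is inactive); a gap is kept
when its low-likelihood count is `>= min_gap_frames`; a bout at exactly
2.5% high-intensity fraction is rejected; a bout of exactly 2.000 s is
kept.

## Numerical choices

* **Zero-phase filtering** uses `scipy.signal.sosfiltfilt`
  (forward-backward, second-order sections). At the very low normalized
  cut-off involved (0.25 Hz at 100 Hz ⇒ Wn = 0.005) the transfer-function
  (b, a) form is numerically unreliable — a pure fs/4 tone leaks through
  with O(1) error — while SOS form is exact.
* **Edge padding** is odd reflection of length `3·fs/cutoff_hz` samples
  (three filter time constants, 12 s at defaults). Pads proportional to
  the coefficient count (the conventional default) are far too short for a
  0.25 Hz filter and leave multi-second edge transients. Traces must be
  longer than three pad lengths (~36 s at 100 Hz defaults) or detrending
  refuses with "trace too short". Even with proper padding, the first and
  last ~1 filter time constant of a recording carry a biased baseline when
  the signal starts mid-oscillation; analyses on whole recordings are
  unaffected, but sample-exact expectations at trace edges are not
  meaningful.
* **Smoothing edges** renormalize the truncated kernel instead of
  zero-padding, so a stationary edge is not dragged toward zero and the
  output length equals the input length.
* **Boundary gaps** (runs of zeros touching either end of the recording)
  are always kept as non-activity regardless of their low-likelihood
  count: there is no surrounding activity into which absorbing them would
  be meaningful.
* **Frame convention**: 0-based, half-open `[start, end)`; durations are
  `(end − start)/fs`.
* **Degenerate inputs**: non-finite samples are rejected at ingestion (an
  optional repair mode linearly interpolates gaps < 1 s and refuses longer
  ones); likelihood values outside [0, 1] and misaligned series raise
  contract errors; an empty comparison cannot be scored.
* **Undefined metrics** (zero denominators) are explicit NaN markers,
  never coerced to 0, and are skipped with a recorded count when averaging
  across participants. Cohort s.d. uses the n−1 denominator.

### A monotonicity caveat

Raising the activity threshold shrinks total *activity* time — provable by
set inclusion through the gap-filter stage, and property-tested. It does
**not** always shrink final *walking* time: the transition heuristic
divides by bout length, so a stricter threshold can split a
transition-contaminated (rejected) bout into a clean surviving walking
bout. The full pipeline is monotone whenever no content approaches the
0.4 g heuristic level, and is tested in that regime.

## What the simulator emulates — and what it does not

`walkbout.simulate` generates the study conditions every test runs on:

* **stationary rest**: a 1 g gravity vector plus i.i.d. per-axis Gaussian
  noise (default σ = 0.012 g for quiet sitting); the detrended magnitude
  of pure noise is chi-distributed with 3 d.o.f. (median 1.5382 σ), which
  gives the calibration recovery tests a closed-form target;
* **walking**: a two-harmonic sinusoid (fundamental on the
  anterior-posterior axis, second harmonic on the vertical, lateral sway)
  with per-sample phase jitter, amplitude ramps, and optional embedded
  pauses for halting gait. Cadence spans 0.5–3.5 Hz, covering very slow
  gait;
* **sit-stand transitions**: an oscillatory vertical transient (push,
  brake, settle) whose lobes cancel pairwise so the event carries no
  content below the detrending cut-off, with peaks 0.3–1 g;
* **orientation**: an arbitrary fixed rotation applied to the whole
  noisy trace, so orientation invariance can be asserted exactly;
* **free-living calibration days**: ~7 h near-silent sleep, ~1 h quiet
  sitting, and ~16 waking hours of sustained low-grade ambient movement
  (σ ≈ 0.055–0.07 g) interleaved with short walks and transitions. Most of
  the day sits in the ambient band, so the 24-h median lands above the
  quiet-rest noise floor (≈ 0.06–0.08 g > 0.05 g), which is what makes the
  personalized variant conservative. A separate `stationary_day` generator
  (noise plus ≤ 5% walking) provides the analytically tractable
  chi-median case.

The default corridor protocol (sit — stand — walk 45 s — sit — rest —
stand — walk back — sit) inserts a ~3 s stabilization rest between each
transition and the adjacent walk: the wearer steadies before stepping off.
This keeps the high-acceleration transient in its own activity bout, where
the 2.5%/0.4 g heuristic can reject it; a transient fused directly onto a
long walk would instead dilute into the walking bout (in both variants
alike).

The simulator does **not** model biomechanical waveform shape, walking-aid
artifacts, non-wear periods, sensor drift or saturation (±8 g clipping),
or annotation latency in ground-truth labels. Passing tests therefore
demonstrate that the staged thresholds behave as specified on signals with
realistic envelope structure — not that the specific metric values carry
over to any real cohort, where noise floors, gait amplitudes and label
quality differ.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
a 10-participant corridor cohort (≈ 4 min of 100 Hz data each) with one
24-h calibration day per participant; 20 random rotations for the
invariance check; 50 random ≤ 100 s traces for brute-force oracle
equivalence; and calibration-recovery runs at 2 h duration (the median
statistic is duration-independent), three noise levels, 20 seeds. The
whole suite completes in about a minute on a single core.

## Known limitations

* The heuristic stage evaluates bouts *after* gap absorption, on their
  full extent; a different ordering (heuristic before absorption) would
  change behaviour on transition-adjacent walking and is not implemented.
* Non-wear detection is out of scope; a day with substantial non-wear
  biases the personalized median low.
* The detector is offline (whole-trace zero-phase filtering); streaming
  operation would need windowed redesign and re-tuned thresholds.
* Step-level gait characteristics (cadence, step length, gait events) are
  out of scope: the output is bouts and per-sample labels only.
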