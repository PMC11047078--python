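# Methods

`scnwave` analyzes multi-day image timeseries of circadian reporters in SCN
(suprachiasmatic nucleus) slice cultures. This note documents the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic validation data do and do not show
about real recordings.

## Signal model and preprocessing

A recording is a stack of grayscale frames at a uniform interval (default
0.5 h, configurable), in hours from the recording start. Two detrending
procedures are used for two different purposes:

- **Moving-average subtraction** (pixel level, before ROI extraction and
  clustering): each pixel trace minus its centered moving average over a
  window of 24.5 h. The window length in frames is `round(window_h /
  frame_interval_h)` forced odd so the window is centered; at the recording
  edges the window shrinks symmetrically to the available frames rather than
  padding — no data are invented at the boundaries where temperature steps
  sit. A window slightly longer than one circadian period passes the
  oscillation (with a small, period-dependent gain change) while removing
  reporter decay and slow drift.
- **Cubic-polynomial subtraction** (whole-tissue traces): the least-squares
  cubic over the analysis window is removed before sinewave fitting.

ROI extraction tiles the image with non-overlapping 3×3-pixel tiles on a
lattice anchored at pixel (0, 0) — the anchor is fixed so cluster maps are
reproducible run to run. A tile is retained when at least half its pixels
(configurable `retention_frac`) lie inside the tissue mask; its trace is the
per-frame mean over the in-mask pixels only. Trailing partial rows/columns
are dropped.

Before clustering, each ROI trace is z-scored (mean 0, SD 1). Z-scoring was
chosen over min-max scaling so the k-means distance is dominated by waveform
shape and phase rather than brightness; min-max (0–100%) normalization is
used instead in the temperature-response stage, where overall expression
change is exactly the quantity of interest. Constant traces cannot be
normalized; they are kept as zeros and flagged degenerate rather than
raising.

## Dominant-sinewave rhythm estimation

A detrended trace is modeled as a single undamped cosine,
`y(t) = A·cos(2π(t − φ)/τ) + baseline(t)`. The period is seeded from the
highest in-band peak of a zero-padded FFT periodogram (band default 16–32 h,
wide enough for short mutant periods and cooling-lengthened periods), then
(A, φ, τ) are refined by Levenberg–Marquardt nonlinear least squares.

Numerical choices:

- The refinement fits the cosine **jointly with a cubic baseline** (on a
  normalized time axis for conditioning). A cubic fitted to an oscillatory
  trace and subtracted beforehand inevitably absorbs part of the oscillation
  and biases the period by ~0.05 h on a 5-day trace; refining the trend
  jointly removes that bias exactly on noise-free inputs, and for traces
  already detrended upstream the cubic terms simply fit ≈ 0.
- The searched period is additionally capped at half the window duration, so
  any reported period completes at least two full cycles in its window.
- A negative fitted amplitude is canonicalized to positive with a half-period
  phase shift.
- A flat spectrum, failed convergence, or an out-of-band refined period
  yields a *nonrhythmic result*, never an exception.

Reported phases: `abs_phase_h` is the first fitted peak after the window
start ("phase to zero"), in [0, τ); `circ_phase_h` rescales it to a
standardized 24-h circadian cycle (`abs_phase_h · 24/τ mod 24`). Cluster
peak times use `abs_phase_h` to control for between-cluster period
differences; cross-reporter lags use `circ_phase_h` on the common 24-h
circle, returned in (−12, +12] h.

Rhythmicity is classified by the relative amplitude error,
RAE = (95% CI half-width of A)/A from the linearized covariance, threshold
0.3 by default (exposed in config and provenance; there is no universal
published criterion). A singular covariance with essentially zero residual
is a perfect fit and gets RAE 0, not infinity. Against 100 seeded white-noise
traces the classifier marks ≥ 95 nonrhythmic at the default threshold.

This is deliberately a single-component undamped fit, not a multi-component
damped decomposition: only the dominant component's period, amplitude and
phase are reported downstream, and damping/drift are handled by the joint
trend term.

**Per-epoch fitting.** Each temperature epoch is fitted independently on its
own clock after discarding the first 12 h of the epoch (configurable
`transient_skip_h`), so the acute transient after a temperature step does
not bias the fit. Epochs retaining fewer than two 24-h cycles of data are
flagged too-short and excluded from period-difference statistics.

## Clustering and wave readouts

K-means with k = 5 (fixed; no model selection), Lloyd iterations, seeded
k-means++ initialization with 10 restarts keeping the best inertia. The
paper-style Lloyd algorithm does not specify initialization; restarts guard
against poor local minima and the seed is recorded for reproducibility. If
the data contain fewer distinct traces than k, k is reduced with a warning.
All ROIs are clustered; the nonrhythmic (NR) label is applied afterwards at
the *cluster* level, to each cluster's mean-trace fit — matching phase maps
in which whole clusters are marked NR.

Cluster centers of mass are computed on the label image
(`scipy.ndimage.center_of_mass`); with uniform tiles this equals the mean of
member ROI centers. The wave vector orders rhythmic clusters by peak time
and regresses COM row and column each on the **phase rank** (0, 1, …);
`angle = atan2(row_slope, col_slope)` is the direction of phase progression
and `r2` the mean of the two regressions' R². Rank was chosen over raw phase
as the regressor because ordinal progression is what the cluster sequence
expresses once period effects are controlled; raw-phase regression is
available as an option. The vector is flagged undefined (not raised) when
fewer than two clusters are rhythmic, when COMs coincide, or when all
rhythmic-cluster peaks fall within one sampling interval of each other — a
synchronous tissue has no resolvable wave direction, and ranking peaks that
differ by less than the frame interval would manufacture one.

## Circular statistics

Phases in hours map to angles by `x = 2π·phase/period`. Cluster phases are
mapped on a **common 24-h circle** (rather than each cluster's own fitted
period) so intercluster dispersion compares like with like; per-period
mapping is available. The dispersion statistic is the circular variance

    circvar = 1 − R̄,  R̄ = √((Σ sin x)² + (Σ cos x)²) / n,

0 for coincident angles, exactly 1 for angles that cancel (e.g. evenly
spaced). The circular mean is `atan2(Σ sin, Σ cos)` with circular SD
`√(−2 ln R̄)`; when R̄ ≈ 0 (antipodal configurations) the mean is flagged
undefined. Period dispersion across clusters is the arithmetic mean and
sample SD (n − 1 denominator) of rhythmic clusters' periods.

## Temperature-response quantification

The whole-tissue trace is min-max normalized over the **full recording**
(largest value 100%, smallest 0%) — not per epoch — so per-epoch slopes are
comparable across epochs and slices; an ordinary least-squares line is then
fitted within each epoch, giving slopes in %/h. Whole-cycle trimming before
the line fit is available as an option but off by default (the line is
fitted through the data as recorded). Δperiod is each epoch's fitted period
minus the unweighted mean over rhythmic epochs, so Δ values sum to zero by
construction. Relative amplitude is the post/pre ratio of fitted amplitudes.
Cross-reporter coupling is the per-epoch OLS of one reporter's per-slice
slopes on the other's, reporting slope, R² and the regression p-value (for
simple OLS the F test equals the two-sided t test on the slope); p-values
are reported per epoch without multiple-testing correction, with a
Bonferroni option in config.

## Synthetic recordings

The generator plants every parameter the analysis estimates, so each stage
has a recovery oracle. A tissue pixel follows

    I(p, t) = y_e · B(t) · [1 + a_e(p) · cos(2π(Θ(t) − φ(p)/τ₀))]

with B(t) a continuous piecewise-linear baseline (slope per epoch, in % of
the oscillation dynamic range 2·amplitude_frac·baseline_level per hour),
Θ(t) the cumulative phase in cycles (instantaneous period τ_e within epoch
e, continuous across steps), φ(p) a linear ramp of peak time along a
configurable wave direction across an elliptical tissue region (one
nucleus), a_e(p) the fractional amplitude (with an optional nonrhythmic
outer border at amplitude 0) and y_e an optional per-epoch photon-yield
factor emulating temperature-dependent luciferase output. Noise is Poisson
on expected counts (bioluminescence-like) or Gaussian (fluorescence-like);
outside the ellipse only background noise is present. A second reporter, if
requested, shares the geometry with phases shifted by `reporter_lag_h`
(default 4 h) and independent noise draws. All randomness comes from one
seeded generator per call.

Defaults emulate the study conditions: 0.5 h frames over 5 days (≥ 3 cycles
are required for stable fitting), 24 h baseline period, fractional amplitude
0.5, baseline 1000 counts, phase span 3 h across the tissue, 37 °C
single-epoch schedule unless a step protocol is supplied.

Two details matter for interpreting recovery tests:

- Because the drift multiplies the oscillation, a steep baseline slope also
  ramps the oscillation amplitude; an amplitude-ramped cosine leaks strongly
  into a straight-line fit, so the *raw* OLS slope of the mean trace is not
  the planted baseline slope under strong drift. The recoverable ground
  truth for the temperature-response stage (`GroundTruth.epoch_slopes`) is
  therefore computed from the generator's own noise-free mean trace on the
  normalized scale, while the planted baseline trend itself is verified on
  the cycle-averaged trace.
- With a *continuous* phase ramp, k-means band boundaries are not
  identifiable (any partition of a continuum is as good as its neighbor), so
  clustering-recovery tests use the `n_phase_bands` option, which quantizes
  the ramp into discrete bands of known membership — an unambiguous oracle.
  The continuous ramp remains the default for phase-map and wave tests.

For cross-reporter regression cohorts the simulation is at the whole-tissue
trace level (the level at which slopes are measured): each slice draws a
cold-induction slope from a normal distribution rectified at zero (slices
range from no to strong induction), reporter b responds with a gain of 1.5
(or 0 in the clock-deletion analog), epochs are 4 days each, and each trace
carries its own oscillation phase and noise.

**What the synthetic data do not show.** The generator plants independent
per-pixel oscillators with a deterministic phase ramp; it contains no
oscillator coupling, no network dynamics, no cell-level heterogeneity beyond
the border option, no optics/PSF blur, no motion, and no damping. Passing
recovery tests therefore demonstrates the correctness of the estimators
under the stated signal model and noise, not robustness to biological
features outside it (e.g. region-specific waveform shape or desynchrony
dynamics).

## Problem sizes used in tests

The test suite and acceptance script run on 32×32–48×48 grids with 168–432
frames, 20-replicate sign tests and 50-cohort regression ensembles; these
sizes give stable statistics for every check while keeping the full suite
fast. Real recordings (hundreds of pixels across, thousands of frames) run
through the same code paths unchanged.

## Known limitations

- The sinewave model is single-component and undamped; strongly damped or
  multi-periodic traces are summarized only by their dominant component.
- The RAE threshold (0.3) and the transient skip (12 h) are defensible
  defaults, not calibrated constants; both are exposed in config and echoed
  in provenance.
- Min-max slope normalization makes slopes of drift-dominated traces
  saturate toward 100%/range; cross-slice comparisons assume broadly similar
  dynamic-range composition.
- No motion correction, flat-field correction or cell segmentation is
  provided; inputs are assumed co-registered.
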