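# scnwave

Spatiotemporal circadian rhythm analysis for image timeseries of SCN
(suprachiasmatic nucleus) slice cultures.

Ex vivo SCN slices expressing bioluminescent or fluorescent circadian
reporters (PER2::LUC, Rbm3-Luc, jRCaMP1a calcium indicators, …) sustain
autonomous ~24 h rhythms that propagate as a spatial phase wave across the
tissue, and respond to temperature steps with changes in expression level,
period and amplitude. `scnwave` turns a multi-day image stack of such a
recording into quantitative readouts:

- **Rhythm parameters** per trace by FFT-seeded nonlinear least squares: the
  dominant sinewave's period τ, amplitude A, peak phase (both "absolute"
  phase in [0, τ) and circadian phase on a 24 h scale), a goodness of fit,
  and a rhythmicity call based on the relative amplitude error
  (RAE = amplitude-CI half-width / amplitude).
- **Spatiotemporal organization** by k-means clustering (k = 5, Lloyd) of
  detrended, z-scored 3×3-pixel ROI timeseries: per-cluster phase maps,
  intercluster circular variance `1 − √((Σ sin x)² + (Σ cos x)²)/n`,
  period dispersion, and a wave-direction vector from linear regression of
  cluster centers of mass against phase order.
- **Temperature responses**: per-epoch slopes of the min-max-normalized
  trace (%/h), Δperiod per epoch relative to the recording mean, post/pre
  relative amplitude, and cross-reporter slope regression across slices
  (R², p).
- **Synthetic recordings** with planted ground truth (phase gradient,
  per-epoch period/amplitude/drift, photon noise, dual reporters with a
  configurable lag) so every stage has a parameter-recovery test.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic 5-day recording (48×48 pixels, 0.5 h frames, planted
period 23.3 h, a 5-band phase wave spanning 8 h, Poisson noise) and analyze
it:

```python
from scnwave import (SynthParams, generate_stack, moving_average_detrend,
                     tile_rois, normalize_series, extract_mean_trace,
                     cubic_detrend, fit_dominant_sinewave, kmeans_timeseries,
                     wave_vector, circular_variance, PhaseSample,
                     period_dispersion)

params = SynthParams(grid_shape=(48, 48), n_frames=240, frame_interval_h=0.5,
                     baseline_period_h=23.3, phase_span_h=8.0, n_phase_bands=5,
                     noise_model="poisson", seed=3)
stack, truth = generate_stack(params)

# whole-tissue rhythm: cubic detrend, then dominant-sinewave fit
trace = extract_mean_trace(stack, truth.tissue_mask)
fit = fit_dominant_sinewave(cubic_detrend(trace), stack.frame_interval_h)
print(f"whole-tissue period: {fit.period_h:.2f} h  (planted 23.30 h)")
print(f"peak phase: {fit.abs_phase_h:.2f} h, RAE {fit.rae:.3f}, rhythmic: {fit.is_rhythmic}")

# spatiotemporal organization: moving-average detrend, 3x3 ROIs, k-means
rois = tile_rois(moving_average_detrend(stack, 24.5), truth.tissue_mask)
norm = normalize_series(rois.series)
result = kmeans_timeseries(rois, k=5, seed=0, series=norm.values)
rhythmic = [f for f in result.fits if f.is_rhythmic]
cv = circular_variance(PhaseSample.from_hours([f.circ_phase_h for f in rhythmic]))
mean_h, sd_h = period_dispersion(rhythmic)
wv = wave_vector(result)
print(f"{rois.n_roi} ROIs -> {result.k} clusters, {len(rhythmic)} rhythmic")
print(f"intercluster circular variance: {cv:.3f}")
print(f"cluster period {mean_h:.2f} +/- {sd_h:.2f} h (SD)")
print(f"wave direction: {wv.angle_deg:.1f} deg (planted 0.0 deg), r2 {wv.r2:.2f}")
```

Output:

```
whole-tissue period: 23.30 h  (planted 23.30 h)
peak phase: 10.00 h, RAE 0.000, rhythmic: True
148 ROIs -> 5 clusters, 5 rhythmic
intercluster circular variance: 0.182
cluster period 23.25 +/- 0.04 h (SD)
wave direction: -0.0 deg (planted 0.0 deg), r2 1.00
```

The fit recovers the planted period exactly at this noise level; the five
clusters reproduce the planted phase bands; the circular variance of 0.18
reflects the 8 h phase span on the 24 h circle; and the wave vector points
along the planted direction of phase progression.

## Command line

The same pipeline runs from a YAML config:

```bash
scnwave all --config cfg.yaml --out runs/r1/
```

with subcommands `simulate`, `preprocess`, `rhythm`, `cluster`, `stats` for
individual stages. Outputs are plain CSV/JSON/TIFF/PNG files plus a
provenance file (config echo, seeds, version, timings) that suffices to
reproduce every number; exit codes are 0 (ok), 2 (config error), 3 (stage
failure). A minimal config:

```yaml
synth:
  grid_shape: [48, 48]
  n_frames: 240
  phase_span_h: 8.0
  n_phase_bands: 5
  seed: 3
cluster:
  k: 5
  seed: 0
```

(or replace `synth:` with `input: {stack: rec.tif, sidecar: rec.json,
mask: mask.tif}` for a real recording).

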