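"""Synthetic SCN-like image-stack generation with known ground truth.

The generator emulates the phenomenology of an ex vivo SCN slice recording:
an elliptical tissue region of per-pixel circadian oscillators riding on a
slowly drifting baseline, with a linear spatial phase gradient (the
dorsomedial-to-ventrolateral wave analog) along a configurable direction,
piecewise-constant temperature effects per epoch (period shift, amplitude
scaling, baseline-slope change, optional photon-yield factor), photon-count
(Poisson) or Gaussian noise, an optional nonrhythmic border, and an optional
second reporter whose phase lags the first by a configurable offset (~4 h by
default, the reporter-vs-calcium lag).

The planted model for a tissue pixel p at time t is

    I(p, t) = y_e * B(t) * [1 + a_e(p) * cos(2*pi*(Theta(t) - phi(p)/tau_0))]

where B(t) is a continuous piecewise-linear baseline, Theta(t) the cumulative
oscillation phase in cycles (slope 1/tau_e within epoch e, so the
instantaneous period is the epoch's), phi(p) the planted peak time in hours,
a_e(p) the fractional amplitude and y_e the epoch photon-yield factor.
Every planted parameter is returned in :class:`GroundTruth` so downstream
stages have a parameter-recovery oracle. No oscillator coupling, network
dynamics or optics are modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .stack_io import FrameStack, TemperatureSchedule

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_stack",
    "write_stack",
    "write_ground_truth",
    "generate_cohort_traces",
]

BACKGROUND_FRAC = 0.02  # background level outside tissue, fraction of baseline_level
ELLIPSE_FRAC = 0.42  # tissue semi-axes as a fraction of the grid dimensions


def _per_epoch(value, n_epochs: int, name: str) -> tuple[float, ...]:
    """Broadcast a scalar or validate a per-epoch sequence."""
    if np.isscalar(value):
        return (float(value),) * n_epochs
    vals = tuple(float(v) for v in value)
    if len(vals) != n_epochs:
        raise ValueError(
            f"{name} has {len(vals)} entries for {n_epochs} temperature epochs"
        )
    return vals


@dataclass
class SynthParams:
    """Planted parameters of a synthetic recording.

    Per-epoch fields accept a scalar (applied to every epoch) or one value
    per temperature epoch. ``baseline_slope_per_epoch`` is in percent of the
    oscillation dynamic range (2 * amplitude_frac * baseline_level) per hour;
    ``period_shift_per_epoch_h`` is added to ``baseline_period_h`` within the
    epoch. The default frame interval of 0.5 h matches half-hourly live
    imaging; it is fully configurable.
    """

    grid_shape: tuple[int, int] = (64, 64)
    n_frames: int = 240
    frame_interval_h: float = 0.5
    baseline_period_h: float = 24.0
    period_shift_per_epoch_h: float | Sequence[float] = 0.0
    amplitude_frac: float = 0.5
    amplitude_scale_per_epoch: float | Sequence[float] = 1.0
    baseline_level: float = 1000.0
    baseline_slope_per_epoch: float | Sequence[float] = 0.0
    photon_yield_per_epoch: float | Sequence[float] = 1.0
    wave_angle_rad: float = 0.0
    phase_span_h: float = 3.0
    phase_offset_h: float = 6.0  # peak time of the earliest tissue pixel
    reporter_lag_h: float = 4.0
    n_phase_bands: int | None = None  # quantize the ramp into discrete bands
    n_reporters: int = 1
    noise_model: str = "poisson"
    gaussian_sd: float = 10.0
    nonrhythmic_border_frac: float = 0.0
    n_clusters_truth: int = 5
    seed: int = 0
    temperature_schedule: TemperatureSchedule | None = None

    def __post_init__(self) -> None:
        if self.temperature_schedule is None:
            self.temperature_schedule = TemperatureSchedule.single(self.duration_h)
        self.validate()

    @property
    def duration_h(self) -> float:
        return self.n_frames * self.frame_interval_h

    @property
    def n_epochs(self) -> int:
        return len(self.temperature_schedule)

    def validate(self) -> None:
        if self.duration_h < 3 * self.baseline_period_h:
            raise ValueError(
                "n_frames * frame_interval_h must cover >= 3 baseline periods "
                f"(got {self.duration_h} h for period {self.baseline_period_h} h)"
            )
        if not 0.0 <= self.amplitude_frac <= 1.0:
            raise ValueError(f"amplitude_frac must be in [0, 1], got {self.amplitude_frac}")
        if not 0.0 <= self.nonrhythmic_border_frac < 1.0:
            raise ValueError(
                f"nonrhythmic_border_frac must be in [0, 1), got {self.nonrhythmic_border_frac}"
            )
        if self.noise_model not in {"poisson", "gaussian"}:
            raise ValueError(f"noise_model must be 'poisson' or 'gaussian', got {self.noise_model!r}")
        if self.n_reporters not in (1, 2):
            raise ValueError(f"n_reporters must be 1 or 2, got {self.n_reporters}")
        span = self.temperature_schedule.total_span_h
        if abs(span - self.duration_h) > 1e-6:
            raise ValueError(
                f"temperature_schedule spans {span} h but the recording spans "
                f"{self.duration_h} h; they must match exactly"
            )
        # trigger broadcast validation
        for name in (
            "period_shift_per_epoch_h",
            "amplitude_scale_per_epoch",
            "baseline_slope_per_epoch",
            "photon_yield_per_epoch",
        ):
            _per_epoch(getattr(self, name), self.n_epochs, name)


@dataclass
class GroundTruth:
    """Every planted parameter of a generated stack, for recovery tests."""

    phase_map_h: np.ndarray  # per-pixel planted peak time (h); NaN outside tissue
    period_per_epoch_h: tuple[float, ...]
    cluster_labels: np.ndarray  # per-pixel planted phase band; -1 outside/nonrhythmic
    wave_angle_rad: float
    epoch_slopes: tuple[float, ...]  # %/h on the min-max-normalized mean trace
    raw_epoch_slopes: tuple[float, ...]  # intensity units per hour, as planted
    rhythmic_mask: np.ndarray  # bool per pixel
    tissue_mask: np.ndarray  # bool per pixel
    mean_trace_noise_free: np.ndarray  # tissue-mean expected intensity per frame
    reporter_lag_h: float
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "period_per_epoch_h": list(self.period_per_epoch_h),
            "wave_angle_rad": self.wave_angle_rad,
            "epoch_slopes_pct_per_h": list(self.epoch_slopes),
            "raw_epoch_slopes": list(self.raw_epoch_slopes),
            "reporter_lag_h": self.reporter_lag_h,
            "seed": self.seed,
            "n_rhythmic_pixels": int(self.rhythmic_mask.sum()),
            "n_tissue_pixels": int(self.tissue_mask.sum()),
        }


def _tissue_geometry(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical tissue mask (one SCN nucleus) and normalized radius map."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cr, ccol = (rows - 1) / 2.0, (cols - 1) / 2.0
    rho = np.sqrt(
        ((rr - cr) / (ELLIPSE_FRAC * rows)) ** 2 + ((cc - ccol) / (ELLIPSE_FRAC * cols)) ** 2
    )
    return rho <= 1.0, rho


def _cumulative_cycles(times_h: np.ndarray, schedule: TemperatureSchedule,
                       periods: Sequence[float]) -> np.ndarray:
    """Oscillation phase in cycles at each frame; continuous across epochs."""
    theta = np.empty_like(times_h)
    acc = 0.0
    for e, epoch in enumerate(schedule):
        sel = (times_h >= epoch.start_h - 1e-9) & (times_h < epoch.end_h - 1e-9)
        theta[sel] = acc + (times_h[sel] - epoch.start_h) / periods[e]
        acc += epoch.duration_h / periods[e]
    return theta


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def generate_stack(params: SynthParams):
    """Generate a synthetic stack (or co-registered pair) and its ground truth.

    Returns ``(FrameStack, GroundTruth)`` for a single reporter, or
    ``((FrameStack, FrameStack), GroundTruth)`` when ``n_reporters == 2``;
    the second reporter's phase map is the first's plus ``reporter_lag_h``
    and its noise is drawn independently. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    schedule = params.temperature_schedule
    n_ep = params.n_epochs
    periods = tuple(
        params.baseline_period_h + s
        for s in _per_epoch(params.period_shift_per_epoch_h, n_ep, "period_shift_per_epoch_h")
    )
    amp_scale = _per_epoch(params.amplitude_scale_per_epoch, n_ep, "amplitude_scale_per_epoch")
    slopes_pct = _per_epoch(params.baseline_slope_per_epoch, n_ep, "baseline_slope_per_epoch")
    yields = _per_epoch(params.photon_yield_per_epoch, n_ep, "photon_yield_per_epoch")

    tissue, rho = _tissue_geometry(params.grid_shape)
    times = np.arange(params.n_frames) * params.frame_interval_h
    epoch_of_frame = np.array([schedule.epoch_index_at(t) for t in times])

    # planted phase: linear ramp along wave_angle across the tissue
    rows, cols = params.grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    proj = np.cos(params.wave_angle_rad) * cc + np.sin(params.wave_angle_rad) * rr
    proj = proj.astype(np.float64)
    pmin, pmax = proj[tissue].min(), proj[tissue].max()
    frac = (proj - pmin) / (pmax - pmin) if pmax > pmin else np.zeros_like(proj)
    band_map = None
    if params.n_phase_bands:
        # discrete phase bands (band-center phases): the unambiguous oracle
        # for clustering-recovery tests; the continuous ramp is the default
        nb = params.n_phase_bands
        band_map = np.clip(np.floor(frac * nb).astype(np.int64), 0, nb - 1)
        frac = (band_map + 0.5) / nb
    phase_map = (params.phase_offset_h + frac * params.phase_span_h) % params.baseline_period_h

    # rhythmic mask: tissue minus the outermost nonrhythmic border fraction
    rhythmic = tissue.copy()
    if params.nonrhythmic_border_frac > 0:
        cut = np.quantile(rho[tissue], 1.0 - params.nonrhythmic_border_frac)
        rhythmic &= rho <= cut
    if params.amplitude_frac == 0:
        rhythmic[:] = False

    # planted cluster bands: the discrete bands if planted, else quantiles of
    # phase among rhythmic pixels
    labels = np.full(params.grid_shape, -1, dtype=np.int64)
    if band_map is not None and rhythmic.any():
        labels[rhythmic] = band_map[rhythmic]
    elif rhythmic.any() and params.phase_span_h > 0:
        k = params.n_clusters_truth
        edges = np.quantile(phase_map[rhythmic], np.linspace(0, 1, k + 1)[1:-1])
        labels[rhythmic] = np.searchsorted(edges, phase_map[rhythmic], side="right")
    elif rhythmic.any():
        labels[rhythmic] = 0

    # continuous piecewise-linear baseline; slope in % of the oscillation
    # dynamic range per hour
    dyn_range = 2.0 * params.amplitude_frac * params.baseline_level
    if dyn_range == 0:
        dyn_range = params.baseline_level
    raw_slopes = tuple(s / 100.0 * dyn_range for s in slopes_pct)
    baseline = np.empty(params.n_frames)
    level = params.baseline_level
    for e, epoch in enumerate(schedule):
        sel = epoch_of_frame == e
        baseline[sel] = level + raw_slopes[e] * (times[sel] - epoch.start_h)
        level += raw_slopes[e] * epoch.duration_h

    theta = _cumulative_cycles(times, schedule, periods)
    amp_map = np.where(rhythmic, params.amplitude_frac, 0.0)
    bg_level = BACKGROUND_FRAC * params.baseline_level
    yield_of_frame = np.array([yields[e] for e in epoch_of_frame])
    amp_scale_of_frame = np.array([amp_scale[e] for e in epoch_of_frame])

    def expected_frames(pmap: np.ndarray) -> np.ndarray:
        cosarg = 2.0 * np.pi * (
            theta[:, None, None] - (pmap[None, :, :] / params.baseline_period_h)
        )
        osc = 1.0 + amp_map[None, :, :] * amp_scale_of_frame[:, None, None] * np.cos(cosarg)
        exp = baseline[:, None, None] * osc
        exp = np.where(tissue[None, :, :], exp, bg_level)
        return exp * yield_of_frame[:, None, None]

    def add_noise(expected: np.ndarray) -> np.ndarray:
        if params.noise_model == "poisson":
            return rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
        noisy = expected + rng.normal(0.0, params.gaussian_sd, size=expected.shape)
        return np.clip(noisy, 0.0, None)

    exp_a = expected_frames(phase_map)
    mean_trace = exp_a[:, tissue].mean(axis=1)
    stack_a = FrameStack(
        frames=add_noise(exp_a),
        frame_interval_h=params.frame_interval_h,
        channel="reporter_a",
    )

    # ground-truth epoch slopes on the min-max-normalized noise-free trace —
    # the scale on which the temperature-response stage reports slopes
    lo, hi = mean_trace.min(), mean_trace.max()
    if hi > lo:
        norm_trace = 100.0 * (mean_trace - lo) / (hi - lo)
        gt_slopes = tuple(
            _ols_slope(times[epoch_of_frame == e], norm_trace[epoch_of_frame == e])
            for e in range(n_ep)
        )
    else:
        gt_slopes = (0.0,) * n_ep

    gt = GroundTruth(
        phase_map_h=np.where(tissue, phase_map, np.nan),
        period_per_epoch_h=periods,
        cluster_labels=labels,
        wave_angle_rad=params.wave_angle_rad,
        epoch_slopes=gt_slopes,
        raw_epoch_slopes=raw_slopes,
        rhythmic_mask=rhythmic,
        tissue_mask=tissue,
        mean_trace_noise_free=mean_trace,
        reporter_lag_h=params.reporter_lag_h if params.n_reporters == 2 else 0.0,
        seed=params.seed,
    )

    if params.n_reporters == 1:
        return stack_a, gt

    phase_b = (phase_map + params.reporter_lag_h) % params.baseline_period_h
    stack_b = FrameStack(
        frames=add_noise(expected_frames(phase_b)),
        frame_interval_h=params.frame_interval_h,
        channel="reporter_b",
    )
    return (stack_a, stack_b), gt


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_stack(
    stack: FrameStack,
    path: str | Path,
    schedule: TemperatureSchedule | None = None,
    seed: int | None = None,
) -> Path:
    """Write a stack as a multi-page 16-bit TIFF plus a JSON metadata sidecar.

    Frames are written in time order, rounded to unsigned 16-bit; a frame
    whose intensities exceed the 16-bit range raises, naming the frame. The
    sidecar (same stem, ``.json``) carries frame_interval_h, channel, t0_h
    and the temperature epochs.
    """
    path = Path(path)
    if stack.n_frames < 1:
        raise ValueError("cannot write an empty stack")
    over = np.flatnonzero(stack.frames.reshape(stack.n_frames, -1).max(axis=1) > 65535)
    if over.size:
        raise ValueError(f"frame {over[0]} exceeds the 16-bit intensity range")
    if stack.frames.min() < 0:
        raise ValueError("negative intensities cannot be written as unsigned 16-bit")
    frames16 = np.round(stack.frames).astype(np.uint16)
    tifffile.imwrite(path, frames16, photometric="minisblack")
    meta = {
        "frame_interval_h": stack.frame_interval_h,
        "channel": stack.channel,
        "t0_h": stack.t0_h,
        "temperature_epochs": schedule.to_dicts() if schedule is not None else [],
    }
    if seed is not None:
        meta["seed"] = int(seed)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    """Write the scalar ground truth as JSON and the per-pixel maps as TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "ground_truth.json").write_text(json.dumps(gt.to_json_dict(), indent=2))
    tifffile.imwrite(out_dir / "phase_map_h.tif", gt.phase_map_h.astype(np.float32))
    tifffile.imwrite(out_dir / "cluster_labels.tif", gt.cluster_labels.astype(np.int16))
    tifffile.imwrite(out_dir / "tissue_mask.tif", gt.tissue_mask.astype(np.uint8))
    tifffile.imwrite(out_dir / "rhythmic_mask.tif", gt.rhythmic_mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# trace-level cohort simulation (cross-reporter slope regression testbed)
# ---------------------------------------------------------------------------


def generate_cohort_traces(
    n_slices: int = 8,
    seed: int = 0,
    shared_induction: bool = True,
    gain_b: float = 1.5,
    induction_mean_pct_per_h: float = 1.5,
    induction_sd_pct_per_h: float = 1.2,
    baseline_level: float = 1000.0,
    osc_amplitude: float = 300.0,
    trace_noise_sd: float = 30.0,
    frame_interval_h: float = 0.5,
    epoch_len_h: float = 96.0,
) -> tuple[list[np.ndarray], list[np.ndarray], TemperatureSchedule, np.ndarray]:
    """Simulate a cohort of dual-reporter whole-tissue traces for
    cross-reporter slope regression.

    Each slice receives a planted cold-induction slope ``u_i`` (percent of
    the oscillation dynamic range per hour, applied during the second
    epoch), drawn from a normal distribution rectified at zero — slices
    range from no induction to strong induction, as between-slice
    variability in reporter responses does. Reporter a responds with slope
    ``u_i``; reporter b with
    ``gain_b * u_i`` when ``shared_induction`` else 0 (the clock-deletion
    analog in which the cold induction of reporter b is ablated). Each
    reporter trace carries its own oscillation phase and independent
    Gaussian noise. Simulation is at the whole-tissue trace level (1-D), not
    the image level, which is the scale on which these slopes are measured.

    Returns (traces_a, traces_b, schedule, planted_inductions).
    """
    rng = np.random.default_rng(seed)
    schedule = TemperatureSchedule(
        [(0.0, epoch_len_h, 37.0), (epoch_len_h, 2 * epoch_len_h, 32.0)]
    )
    n = int(round(2 * epoch_len_h / frame_interval_h))
    t = np.arange(n) * frame_interval_h
    cold = t >= epoch_len_h
    dyn_range = 2.0 * osc_amplitude
    u = np.maximum(rng.normal(induction_mean_pct_per_h, induction_sd_pct_per_h, size=n_slices), 0.0)

    traces_a: list[np.ndarray] = []
    traces_b: list[np.ndarray] = []
    for i in range(n_slices):
        for target, slope_pct in (
            (traces_a, u[i]),
            (traces_b, gain_b * u[i] if shared_induction else 0.0),
        ):
            phase = rng.uniform(0, 24)
            drift = np.where(cold, slope_pct / 100.0 * dyn_range * (t - epoch_len_h), 0.0)
            trace = (
                baseline_level
                + drift
                + osc_amplitude * np.cos(2 * np.pi * (t - phase) / 24.0)
                + rng.normal(0, trace_noise_sd, size=n)
            )
            target.append(trace)
    return traces_a, traces_b, schedule, u
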