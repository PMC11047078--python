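"""Dominant-sinewave rhythm estimation by FFT-seeded nonlinear least squares.

A detrended trace is modeled as a single undamped cosine plus offset,

    y(t) = A cos(2*pi*(t - phi)/tau) + c,

with the period ``tau`` seeded from the highest in-band peak of a zero-padded
periodogram and all four parameters refined by nonlinear least squares.
Damping and slow drift are assumed to have been removed by detrending, so a
single component suffices to report the circadian period, amplitude and peak
phase of a trace.

Phase conventions: ``abs_phase_h`` is the time of the first fitted peak after
the start of the analysis window ("phase to zero"), in [0, period);
``circ_phase_h`` rescales it to a standardized 24-h circadian cycle,
``abs_phase_h * 24 / period mod 24``.

Rhythmicity is classified by the relative amplitude error (RAE): the
half-width of the ~95% confidence interval of the fitted amplitude divided by
the amplitude. Traces with RAE above a threshold (default 0.3), or whose
refined period escapes the search band, are nonrhythmic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .stack_io import TemperatureSchedule, cubic_detrend

__all__ = [
    "RhythmFit",
    "EpochFit",
    "fit_dominant_sinewave",
    "fit_per_epoch",
    "phase_offset",
]

DEFAULT_BAND_H = (16.0, 32.0)
DEFAULT_RAE_THRESHOLD = 0.3


@dataclass
class RhythmFit:
    """Parameters of the dominant fitted sinewave of one trace."""

    period_h: float
    amplitude: float
    abs_phase_h: float
    circ_phase_h: float
    rae: float
    gof: float
    is_rhythmic: bool
    offset: float = 0.0
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "period_h": self.period_h,
            "amplitude": self.amplitude,
            "abs_phase_h": self.abs_phase_h,
            "circ_phase_h": self.circ_phase_h,
            "rae": self.rae,
            "gof": self.gof,
            "is_rhythmic": self.is_rhythmic,
        }


@dataclass
class EpochFit:
    epoch_index: int
    start_h: float
    end_h: float
    temp_c: float
    fit: RhythmFit | None
    too_short: bool = False


def _nonrhythmic(flag: str) -> RhythmFit:
    return RhythmFit(
        period_h=math.nan,
        amplitude=0.0,
        abs_phase_h=math.nan,
        circ_phase_h=math.nan,
        rae=math.inf,
        gof=0.0,
        is_rhythmic=False,
        flags=(flag,),
    )


def _cosine(t, amp, phase, period, offset):
    return amp * np.cos(2.0 * np.pi * (t - phase) / period) + offset


def _make_model(t_norm: np.ndarray):
    """Cosine plus cubic baseline. Refining the trend jointly with the
    sinewave keeps residual trend left over by upstream detrending (which a
    cubic fitted to an oscillatory trace inevitably leaves or removes
    unevenly) from biasing the period and phase estimates; the baseline uses
    a normalized time axis for conditioning."""

    def model(t, amp, phase, period, c0, c1, c2, c3):
        return amp * np.cos(2.0 * np.pi * (t - phase) / period) + np.polyval(
            [c3, c2, c1, c0], t_norm
        )

    return model


def _fft_candidate(
    trace: np.ndarray, dt_h: float, band: tuple[float, float]
) -> tuple[float, float, float] | None:
    """Seed (period, phase, amplitude) from the dominant in-band FFT peak.

    The periodogram is zero-padded so the frequency grid resolves periods to
    well under 0.1 h near 24 h; the nonlinear refinement removes the residual
    grid quantization.
    """
    n = trace.size
    n_pad = max(8192, 1 << int(np.ceil(np.log2(16 * n))))
    spec = np.fft.rfft(trace - trace.mean(), n=n_pad)
    freqs = np.fft.rfftfreq(n_pad, d=dt_h)
    with np.errstate(divide="ignore"):
        in_band = (freqs > 0) & (freqs >= 1.0 / band[1]) & (freqs <= 1.0 / band[0])
    if not in_band.any():
        return None
    power = np.abs(spec) ** 2
    if power[in_band].max() == 0.0:
        return None
    k = np.flatnonzero(in_band)[np.argmax(power[in_band])]
    period = 1.0 / freqs[k]
    # amplitude and phase of the cosine at the peak frequency
    amp = 2.0 * np.abs(spec[k]) / n
    phase = (-np.angle(spec[k])) * period / (2.0 * np.pi) % period
    return period, phase, amp


def fit_dominant_sinewave(
    trace: np.ndarray,
    frame_interval_h: float,
    band_h: tuple[float, float] = DEFAULT_BAND_H,
    rae_threshold: float = DEFAULT_RAE_THRESHOLD,
) -> RhythmFit:
    """Fit the dominant circadian cosine to a detrended trace.

    The trace is assumed detrended (mean approximately 0, no slow drift).
    Times are measured from the first sample of the trace, so ``abs_phase_h``
    is the first fitted peak after the window start. The searched period band
    is additionally capped at half the trace duration so any reported period
    completes at least two full cycles.

    A flat spectrum, a failed refinement, or an out-of-band refined period
    yields a nonrhythmic result (never an exception).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("expected a 1-D trace")
    n = trace.size
    duration = n * frame_interval_h
    lo, hi = float(band_h[0]), min(float(band_h[1]), duration / 2.0)
    if lo >= hi or n < 8:
        return _nonrhythmic("window_too_short")
    if np.ptp(trace) == 0.0:
        return _nonrhythmic("flat_trace")

    seed = _fft_candidate(trace, frame_interval_h, (lo, hi))
    if seed is None:
        return _nonrhythmic("no_spectral_peak_in_band")
    period0, phase0, amp0 = seed

    t = np.arange(n) * frame_interval_h
    t_norm = (t - t.mean()) / (t.max() / 2.0)
    model = _make_model(t_norm)
    seed_cos = _cosine(t, amp0, phase0, period0, 0.0)
    poly0 = np.polynomial.polynomial.polyfit(t_norm, trace - seed_cos, deg=3)
    p0 = [max(amp0, 1e-12), phase0, period0, *poly0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, t, trace, p0=p0, method="lm", maxfev=10000
            )
    except RuntimeError:
        return _nonrhythmic("solver_failed")
    amp, phase, period = popt[:3]
    offset = popt[3]
    if not np.all(np.isfinite(popt)):
        return _nonrhythmic("solver_failed")
    if amp < 0:  # canonicalize: positive amplitude, phase shifted by half period
        amp = -amp
        phase += period / 2.0
    period = abs(period)

    resid = trace - model(t, amp, phase, period, *popt[3:])
    sst = float(np.sum((trace - trace.mean()) ** 2))
    ssr = float(np.sum(resid**2))
    gof = 1.0 - ssr / sst if sst > 0 else 0.0

    # RAE: 95% CI half-width of A over A, from the linearized covariance.
    # A singular covariance with essentially zero residual is a perfect fit
    # (zero amplitude uncertainty), not an unreliable one.
    if np.all(np.isfinite(pcov)):
        var_amp = float(pcov[0, 0])
    elif ssr <= 1e-10 * max(sst, 1.0):
        var_amp = 0.0
    else:
        var_amp = math.inf
    rae = 1.96 * math.sqrt(max(var_amp, 0.0)) / amp if amp > 0 else math.inf

    abs_phase = phase % period
    circ_phase = (abs_phase * 24.0 / period) % 24.0
    in_band = (band_h[0] - 1e-9) <= period <= (band_h[1] + 1e-9)
    return RhythmFit(
        period_h=float(period),
        amplitude=float(amp),
        abs_phase_h=float(abs_phase),
        circ_phase_h=float(circ_phase),
        rae=float(rae),
        gof=float(gof),
        is_rhythmic=bool(rae <= rae_threshold and in_band),
        offset=float(offset),
    )


def fit_per_epoch(
    trace: np.ndarray,
    frame_interval_h: float,
    schedule: TemperatureSchedule,
    transient_skip_h: float = 12.0,
    band_h: tuple[float, float] = DEFAULT_BAND_H,
    rae_threshold: float = DEFAULT_RAE_THRESHOLD,
    min_cycles: float = 2.0,
    detrend: bool = True,
) -> list[EpochFit]:
    """Fit each temperature epoch independently.

    The first ``transient_skip_h`` hours of every epoch are discarded so the
    acute transient after a temperature step does not bias the fit. Each
    remaining window is cubic-detrended and fitted on its own clock (phase
    zero = first retained frame of the epoch). Windows shorter than
    ``min_cycles`` circadian cycles (24 h each) are flagged ``too_short`` and
    carry no fit; downstream period-difference statistics skip them.
    """
    if schedule is None:
        raise ValueError("temperature schedule required for per-epoch fitting")
    trace = np.asarray(trace, dtype=np.float64)
    out: list[EpochFit] = []
    for i, epoch in enumerate(schedule):
        w0 = epoch.start_h + transient_skip_h
        i0 = int(np.ceil(w0 / frame_interval_h - 1e-9))
        i1 = min(int(np.floor(epoch.end_h / frame_interval_h + 1e-9)), trace.size)
        window = trace[i0:i1]
        if window.size * frame_interval_h < min_cycles * 24.0 or window.size < 8:
            out.append(EpochFit(i, epoch.start_h, epoch.end_h, epoch.temp_c, None, True))
            continue
        detrended = cubic_detrend(window) if detrend else window
        fit = fit_dominant_sinewave(detrended, frame_interval_h, band_h, rae_threshold)
        out.append(EpochFit(i, epoch.start_h, epoch.end_h, epoch.temp_c, fit, False))
    return out


def phase_offset(fit_a: RhythmFit, fit_b: RhythmFit) -> float:
    """Circular phase difference b - a on the 24-h circadian circle.

    Returned in (-12, +12] h; positive means reporter b peaks after reporter
    a. Both fits must be rhythmic.
    """
    if not (fit_a.is_rhythmic and fit_b.is_rhythmic):
        raise ValueError("phase_offset requires two rhythmic fits")
    d = (fit_b.circ_phase_h - fit_a.circ_phase_h) % 24.0
    if d > 12.0:
        d -= 24.0
    return d
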