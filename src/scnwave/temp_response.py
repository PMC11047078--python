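"""Quantification of temperature-evoked reporter-expression changes.

Four readouts: (1) per-epoch linear slope of the min-max-normalized
whole-tissue trace (0-100% of the recording's dynamic range, so slopes are
in %/h and comparable across epochs and slices); (2) per-epoch period
difference relative to the recording-mean period (delta period); (3) the
post/pre relative amplitude of a perturbation; and (4) ordinary
least-squares regression of one reporter's per-slice slopes on another's,
the cross-reporter coupling readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .rhythm import EpochFit, RhythmFit
from .stack_io import TemperatureSchedule

__all__ = [
    "EpochSlope",
    "RegressionResult",
    "epoch_slopes",
    "delta_period",
    "relative_amplitude",
    "cross_reporter_regression",
]


@dataclass
class EpochSlope:
    epoch_id: int
    slope: float  # % of full-recording dynamic range per hour
    intercept: float  # %
    r2: float
    n_frames_used: int
    temp_c: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def epoch_slopes(
    trace: np.ndarray,
    frame_interval_h: float,
    schedule: TemperatureSchedule,
    transient_skip_h: float = 0.0,
) -> list[EpochSlope]:
    """Fit a line through the normalized trace within each temperature epoch.

    The trace is min-max normalized over the FULL recording (largest value
    100%, smallest 0%), then an ordinary least-squares line is fitted
    independently within each epoch; the slope (%/h) summarizes the overall
    temperature-dependent drift of reporter expression in that epoch.
    ``transient_skip_h`` optionally discards the first hours of each epoch.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("expected a 1-D trace")
    if schedule is None:
        raise ValueError("temperature schedule required")
    span = schedule.total_span_h
    if trace.size * frame_interval_h < span - 1e-6:
        raise ValueError(
            f"trace ({trace.size * frame_interval_h} h) does not span the schedule ({span} h)"
        )
    rng = np.ptp(trace)
    if rng == 0:
        raise ValueError("constant trace cannot be normalized")
    norm = 100.0 * (trace - trace.min()) / rng

    t = np.arange(trace.size) * frame_interval_h
    out: list[EpochSlope] = []
    for i, epoch in enumerate(schedule):
        sel = (t >= epoch.start_h + transient_skip_h - 1e-9) & (t < epoch.end_h - 1e-9)
        n_used = int(sel.sum())
        if n_used < 3:
            raise ValueError(f"epoch {i} has {n_used} frames; need >= 3 for a line fit")
        res = stats.linregress(t[sel], norm[sel])
        out.append(
            EpochSlope(
                epoch_id=i,
                slope=float(res.slope),
                intercept=float(res.intercept),
                r2=float(res.rvalue**2),
                n_frames_used=n_used,
                temp_c=epoch.temp_c,
            )
        )
    return out


def delta_period(per_epoch_fits: Sequence[EpochFit]) -> list[tuple[int, float]]:
    """Per-epoch period minus the unweighted mean period of rhythmic epochs.

    Too-short and nonrhythmic epochs are excluded from the mean and receive
    no delta. The returned deltas sum to zero by construction.
    """
    usable = [
        ef
        for ef in per_epoch_fits
        if not ef.too_short and ef.fit is not None and ef.fit.is_rhythmic
    ]
    if len(usable) < 2:
        raise ValueError(f"delta_period needs >= 2 rhythmic epochs, got {len(usable)}")
    mean_period = float(np.mean([ef.fit.period_h for ef in usable]))
    return [(ef.epoch_index, ef.fit.period_h - mean_period) for ef in usable]


def relative_amplitude(pre_fit: RhythmFit, post_fit: RhythmFit) -> float:
    """Post/pre fitted-amplitude ratio of a perturbation."""
    if pre_fit is None or post_fit is None:
        raise ValueError("both windows must be fitted")
    if not pre_fit.is_rhythmic:
        raise ValueError("pre window is nonrhythmic; relative amplitude undefined")
    if pre_fit.amplitude <= 0:
        raise ValueError("pre amplitude must be positive")
    return float(post_fit.amplitude / pre_fit.amplitude)


def _regress(a: np.ndarray, b: np.ndarray) -> RegressionResult:
    res = stats.linregress(a, b)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=a.size,
    )


def cross_reporter_regression(
    slopes_a: Sequence[float],
    slopes_b: Sequence[float],
    by_epoch: Sequence | None = None,
) -> dict:
    """OLS of reporter-b slopes on reporter-a slopes across slices.

    ``slopes_a``/``slopes_b`` are paired per-slice values. With ``by_epoch``
    (an epoch label per pair), a regression is run within each epoch and a
    pooled regression over all pairs; without it a single regression is
    returned under the key ``"pooled"``. Each result carries the fitted
    line, R^2 and the regression p-value (for simple OLS the F test equals
    the two-sided t test on the slope).
    """
    a = np.asarray(slopes_a, dtype=np.float64)
    b = np.asarray(slopes_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("slopes_a and slopes_b must be paired 1-D sequences")
    results: dict = {}
    if by_epoch is not None:
        labels = np.asarray(by_epoch)
        if labels.shape != a.shape:
            raise ValueError("by_epoch must label every pair")
        for lab in np.unique(labels):
            sel = labels == lab
            if sel.sum() < 3:
                raise ValueError(f"epoch {lab!r} has {int(sel.sum())} pairs; need >= 3")
            results[lab] = _regress(a[sel], b[sel])
    if a.size < 3:
        raise ValueError(f"need >= 3 paired slopes, got {a.size}")
    results["pooled"] = _regress(a, b)
    return results
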