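"""Circular statistics on cluster phases and wave-vector angles.

Phases in hours are mapped to angles by x = 2*pi*phase_h/period_h on a common
circadian circle (default 24 h, so phases of clusters with slightly different
fitted periods remain comparable). The dispersion statistic is the circular
variance

    circvar = 1 - Rbar,   Rbar = sqrt((sum sin x)^2 + (sum cos x)^2) / n,

which is 0 when all angles coincide and 1 when they cancel (e.g. evenly
spaced around the circle). The circular mean is atan2(sum sin, sum cos) with
circular SD sqrt(-2 ln Rbar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PhaseSample",
    "CircularMean",
    "hours_to_radians",
    "radians_to_hours",
    "circular_variance",
    "circular_mean",
    "period_dispersion",
]

_EPS_RBAR = 1e-12


def _wrap(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(x, dtype=np.float64) + np.pi) % (2 * np.pi) - np.pi)


def hours_to_radians(phase_h, period_h: float = 24.0) -> np.ndarray:
    return _wrap(2.0 * np.pi * np.asarray(phase_h, dtype=np.float64) / period_h)


def radians_to_hours(x, period_h: float = 24.0) -> np.ndarray:
    return (np.asarray(x, dtype=np.float64) * period_h / (2.0 * np.pi)) % period_h


@dataclass
class PhaseSample:
    """A sample of angles for circular statistics.

    ``source`` records whether the angles came from cluster peak phases or
    wave-vector directions; ``period_h`` is the circle used for the
    hours-to-radians mapping when the sample was built from phases in hours.
    """

    values_rad: np.ndarray
    source: str = "cluster_phase"
    period_h: float = 24.0

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values_rad, dtype=np.float64))
        if v.size < 1:
            raise ValueError("PhaseSample needs at least one angle")
        self.values_rad = _wrap(v)

    @classmethod
    def from_hours(
        cls, phase_h: Sequence[float], period_h: float = 24.0, source: str = "cluster_phase"
    ) -> "PhaseSample":
        return cls(hours_to_radians(phase_h, period_h), source=source, period_h=period_h)

    @property
    def n(self) -> int:
        return self.values_rad.size

    def resultant_length(self) -> float:
        s = np.sin(self.values_rad).sum()
        c = np.cos(self.values_rad).sum()
        return float(math.hypot(s, c) / self.n)


def circular_variance(sample: PhaseSample) -> float:
    """Circular variance 1 - Rbar, in [0, 1]."""
    return min(max(1.0 - sample.resultant_length(), 0.0), 1.0)


@dataclass
class CircularMean:
    mean_rad: float
    mean_h: float
    sd_rad: float
    sd_h: float
    defined: bool


def circular_mean(sample: PhaseSample) -> CircularMean:
    """Circular mean direction with circular SD.

    When the mean resultant length is ~0 (e.g. an antipodal pair) the mean
    direction is undefined; the result is flagged rather than raising.
    """
    s = float(np.sin(sample.values_rad).sum())
    c = float(np.cos(sample.values_rad).sum())
    rbar = math.hypot(s, c) / sample.n
    if rbar < _EPS_RBAR:
        return CircularMean(math.nan, math.nan, math.nan, math.nan, False)
    mean = float(_wrap(math.atan2(s, c)))
    sd = math.sqrt(-2.0 * math.log(min(rbar, 1.0))) if rbar < 1.0 else 0.0
    factor = sample.period_h / (2.0 * math.pi)
    return CircularMean(
        mean_rad=mean,
        mean_h=float(radians_to_hours(mean, sample.period_h)),
        sd_rad=sd,
        sd_h=sd * factor,
        defined=True,
    )


def period_dispersion(fits: Iterable) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the periods of rhythmic fits.

    Nonrhythmic fits are excluded; at least two rhythmic fits are required
    for the SD to be defined.
    """
    periods = [f.period_h for f in fits if getattr(f, "is_rhythmic", False)]
    if len(periods) < 2:
        raise ValueError(f"period dispersion needs >= 2 rhythmic fits, got {len(periods)}")
    arr = np.asarray(periods, dtype=np.float64)
    return float(arr.mean()), float(arr.std(ddof=1))
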