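"""Image-stack containers, detrending, and ROI-grid extraction.

This module holds the in-memory containers for a reporter's image timeseries
(:class:`FrameStack`), the temperature step protocol
(:class:`TemperatureSchedule`), and the per-ROI trace matrix
(:class:`RoiSeriesSet`), together with the two detrending procedures used in
SCN imaging analysis (a centered moving-average subtraction for pixel-level
work and a cubic-polynomial subtraction for whole-tissue traces) and the
3x3-pixel ROI tiling that turns an image stack into a matrix of timeseries.

All time bookkeeping is in hours from the start of the recording; frame
indices never cross module boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "TemperatureEpoch",
    "TemperatureSchedule",
    "RoiSeriesSet",
    "NormalizedSeries",
    "read_stack",
    "read_mask",
    "moving_average_detrend",
    "cubic_detrend",
    "tile_rois",
    "extract_mean_trace",
    "normalize_series",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FrameStack:
    """A single reporter's image timeseries with uniform frame interval.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Intensity values, nonnegative. Stored as float64 internally so the
        detrending operations (which produce signed residuals) can reuse the
        same container.
    frame_interval_h : float
        Hours between consecutive frames (> 0).
    channel : str
        Reporter label, e.g. ``"PER2::LUC"`` or ``"jRCaMP1a"``.
    t0_h : float
        Time of the first frame relative to the recording start, hours.
    """

    frames: np.ndarray
    frame_interval_h: float
    channel: str = ""
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, rows, cols); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameStack needs at least 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_h(self) -> float:
        """Total span of the recording, first to one-past-last frame."""
        return self.n_frames * self.frame_interval_h

    @property
    def times_h(self) -> np.ndarray:
        return self.t0_h + np.arange(self.n_frames) * self.frame_interval_h


@dataclass(frozen=True)
class TemperatureEpoch:
    start_h: float
    end_h: float
    temp_c: float

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass
class TemperatureSchedule:
    """Ordered, contiguous, non-overlapping temperature epochs.

    The first epoch starts at hour 0 of the recording; epochs partition the
    recording without gaps.
    """

    epochs: list[TemperatureEpoch]

    def __post_init__(self) -> None:
        eps = [
            e if isinstance(e, TemperatureEpoch) else TemperatureEpoch(*e)
            for e in self.epochs
        ]
        if not eps:
            raise ValueError("schedule needs at least one epoch")
        if abs(eps[0].start_h) > 1e-9:
            raise ValueError("first epoch must start at hour 0")
        for a, b in zip(eps, eps[1:]):
            if abs(a.end_h - b.start_h) > 1e-9:
                raise ValueError(
                    f"epochs must be contiguous: epoch ending at {a.end_h} h "
                    f"followed by epoch starting at {b.start_h} h"
                )
        for e in eps:
            if e.end_h <= e.start_h:
                raise ValueError(f"epoch {e} has nonpositive duration")
        self.epochs = eps

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def total_span_h(self) -> float:
        return self.epochs[-1].end_h

    def epoch_index_at(self, t_h: float) -> int:
        """Index of the epoch containing time ``t_h`` (end-exclusive except last)."""
        for i, e in enumerate(self.epochs):
            if e.start_h - 1e-9 <= t_h < e.end_h - 1e-9:
                return i
        if t_h <= self.total_span_h + 1e-9:
            return len(self.epochs) - 1
        raise ValueError(f"time {t_h} h outside schedule span {self.total_span_h} h")

    def to_dicts(self) -> list[dict]:
        return [
            {"start_h": e.start_h, "end_h": e.end_h, "temp_c": e.temp_c}
            for e in self.epochs
        ]

    @classmethod
    def from_dicts(cls, dicts: Sequence[dict]) -> "TemperatureSchedule":
        return cls([TemperatureEpoch(d["start_h"], d["end_h"], d["temp_c"]) for d in dicts])

    @classmethod
    def single(cls, span_h: float, temp_c: float = 37.0) -> "TemperatureSchedule":
        return cls([TemperatureEpoch(0.0, span_h, temp_c)])


@dataclass
class RoiSeriesSet:
    """Matrix of per-ROI traces on a fixed square-tile lattice.

    ``series`` has one row per retained ROI; ``roi_centers`` gives the
    (row, col) center pixel of each tile, 0-based; ``mask_fraction`` the
    fraction of each tile's pixels inside the tissue mask.
    """

    series: np.ndarray  # (n_roi, n_frames)
    roi_centers: np.ndarray  # (n_roi, 2) int
    roi_size: int
    mask_fraction: np.ndarray  # (n_roi,)
    frame_interval_h: float
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        self.roi_centers = np.asarray(self.roi_centers, dtype=np.int64)
        self.mask_fraction = np.asarray(self.mask_fraction, dtype=np.float64)
        if self.series.ndim != 2:
            raise ValueError("series must be 2-D (n_roi, n_frames)")
        n = self.series.shape[0]
        if self.roi_centers.shape != (n, 2) or self.mask_fraction.shape != (n,):
            raise ValueError("roi_centers / mask_fraction shapes inconsistent with series")

    @property
    def n_roi(self) -> int:
        return self.series.shape[0]

    @property
    def times_h(self) -> np.ndarray:
        return self.t0_h + np.arange(self.series.shape[1]) * self.frame_interval_h


@dataclass
class NormalizedSeries:
    """Normalized trace matrix plus a per-row degenerate (constant-input) flag."""

    values: np.ndarray
    degenerate: np.ndarray  # bool per row
    mode: str


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_stack(path: str | Path, sidecar_path: str | Path | None = None) -> tuple[
    FrameStack, TemperatureSchedule | None
]:
    """Read a multi-page TIFF stack plus its JSON metadata sidecar.

    The sidecar must provide ``frame_interval_h`` (the loader refuses to guess
    a sampling interval); ``temperature_epochs`` is optional — schedule-
    dependent operations downstream will refuse to run without it.

    Returns the stack and the schedule (``None`` if absent from the sidecar).
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if "frame_interval_h" not in meta:
        raise ValueError(f"sidecar {sidecar_path} lacks required key 'frame_interval_h'")

    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            for i, p in enumerate(tif.pages):
                if p.shape != tif.pages[0].shape:
                    raise ValueError(
                        f"TIFF page {i} has shape {p.shape}, expected {tif.pages[0].shape}"
                    )
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]

    stack = FrameStack(
        frames=frames.astype(np.float64),
        frame_interval_h=float(meta["frame_interval_h"]),
        channel=str(meta.get("channel", "")),
        t0_h=float(meta.get("t0_h", 0.0)),
    )
    schedule = None
    if meta.get("temperature_epochs"):
        schedule = TemperatureSchedule.from_dicts(meta["temperature_epochs"])
    return stack, schedule


def read_mask(path: str | Path) -> np.ndarray:
    """Read a tissue mask image (TIFF/PNG, nonzero = tissue) as boolean."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path))
    if img.ndim == 3:  # RGB(A) -> any channel nonzero
        img = img.max(axis=-1)
    return np.asarray(img) != 0


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------


def _moving_average_shrinking(x: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average along axis 0 with a symmetrically shrinking
    window at the edges (at index i the half-width is min(half, i, n-1-i))."""
    n = x.shape[0]
    cs = np.cumsum(x, axis=0, dtype=np.float64)
    cs = np.concatenate([np.zeros((1,) + x.shape[1:]), cs], axis=0)
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h + 1
    width = (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    return (cs[hi] - cs[lo]) / width


def moving_average_detrend(stack: FrameStack, window_h: float = 24.5) -> FrameStack:
    """Subtract a centered moving average from every pixel trace.

    The window length in frames is ``round(window_h / frame_interval_h)``
    forced odd so the window is centered; at the recording edges the window
    shrinks symmetrically to the available frames (no padding, no invented
    data at the boundaries where temperature steps occur).
    """
    if window_h >= stack.duration_h:
        raise ValueError(
            f"window_h={window_h} h must be shorter than the recording "
            f"({stack.duration_h} h)"
        )
    w = int(round(window_h / stack.frame_interval_h))
    if w % 2 == 0:
        w += 1
    w = max(w, 3)
    half = w // 2
    trend = _moving_average_shrinking(stack.frames, half)
    return replace(stack, frames=stack.frames - trend)


def cubic_detrend(trace: np.ndarray, times_h: np.ndarray | None = None) -> np.ndarray:
    """Subtract the least-squares cubic polynomial from a 1-D trace.

    The standard whole-tissue preprocessing step: removes reporter decay and
    slow baseline drift before sinewave fitting. Requires >= 5 points so the
    cubic is overdetermined.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("cubic_detrend expects a 1-D trace")
    n = trace.size
    if n < 5:
        raise ValueError(f"cubic detrend needs >= 5 points, got {n}")
    t = np.arange(n, dtype=np.float64) if times_h is None else np.asarray(times_h, float)
    poly = np.polynomial.Polynomial.fit(t, trace, deg=3)
    return trace - poly(t)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------


def tile_rois(
    stack: FrameStack,
    mask: np.ndarray,
    roi_size: int = 3,
    retention_frac: float = 0.5,
) -> RoiSeriesSet:
    """Tile the image into non-overlapping ``roi_size`` x ``roi_size`` ROIs.

    The tile lattice is anchored at pixel (0, 0); trailing partial rows/cols
    are dropped (floor division). Each retained ROI's trace is the per-frame
    mean over the tile's in-mask pixels; tiles whose in-mask pixel fraction is
    below ``retention_frac`` are dropped. ROI centers are the tile's center
    pixel, 0-based (row, col).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {stack.frame_shape}"
        )
    if not mask.any():
        raise ValueError("tissue mask is empty")

    rows, cols = mask.shape
    nr, nc = rows // roi_size, cols // roi_size
    series, centers, fracs = [], [], []
    n_px = roi_size * roi_size
    for i in range(nr):
        for j in range(nc):
            r0, c0 = i * roi_size, j * roi_size
            tile_mask = mask[r0 : r0 + roi_size, c0 : c0 + roi_size]
            frac = tile_mask.sum() / n_px
            if frac < retention_frac or not tile_mask.any():
                continue
            tile = stack.frames[:, r0 : r0 + roi_size, c0 : c0 + roi_size]
            series.append(tile[:, tile_mask].mean(axis=1))
            centers.append((r0 + roi_size // 2, c0 + roi_size // 2))
            fracs.append(frac)
    if not series:
        raise ValueError("no ROI retained: mask too sparse for the retention threshold")
    return RoiSeriesSet(
        series=np.array(series),
        roi_centers=np.array(centers),
        roi_size=roi_size,
        mask_fraction=np.array(fracs),
        frame_interval_h=stack.frame_interval_h,
        t0_h=stack.t0_h,
    )


def extract_mean_trace(stack: FrameStack, mask: np.ndarray) -> np.ndarray:
    """Per-frame mean intensity over the in-mask pixels (the whole-tissue trace)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frame_shape:
        raise ValueError("mask shape does not match frame shape")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    return stack.frames[:, mask].mean(axis=1)


def normalize_series(series: np.ndarray, mode: str = "zscore") -> NormalizedSeries:
    """Normalize each trace (row) of a trace matrix.

    ``zscore`` (default, used before K-means so clustering groups by waveform
    shape and phase rather than brightness): per-row mean 0, SD 1.
    ``minmax``: per-row 0-100% of the row's dynamic range (the temperature-
    response convention).

    Constant rows cannot be normalized; they are kept as all-zeros and flagged
    in ``degenerate`` rather than raising.
    """
    x = np.atleast_2d(np.asarray(series, dtype=np.float64))
    if mode == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        degenerate = sd[:, 0] == 0
        sd[degenerate] = 1.0
        out = (x - mu) / sd
        out[degenerate] = 0.0
    elif mode == "minmax":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        rng = hi - lo
        degenerate = rng[:, 0] == 0
        rng[degenerate] = 1.0
        out = 100.0 * (x - lo) / rng
        out[degenerate] = 0.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if np.asarray(series).ndim == 1:
        return NormalizedSeries(out[0], degenerate, mode)
    return NormalizedSeries(out, degenerate, mode)
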