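"""K-means clustering of ROI timeseries and spatiotemporal wave readouts.

Normalized per-ROI traces are grouped with k-means (k = 5 by default, Lloyd
iterations, seeded k-means++ restarts). Each cluster's mean trace is fitted
with the dominant-sinewave model; clusters whose mean trace fails the
rhythmicity criterion are labeled NR. The spatial progression of the phase
wave is summarized by regressing the cluster centers of mass against the
clusters' phase order and reporting the direction of travel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from . import rhythm
from .stack_io import RoiSeriesSet

__all__ = ["ClusterResult", "WaveVector", "kmeans_timeseries", "cluster_phase_map", "wave_vector"]


@dataclass
class ClusterResult:
    """ROI->cluster assignment with per-cluster rhythm fits and geometry."""

    k: int
    labels: np.ndarray  # (n_roi,) cluster index
    mean_series: np.ndarray  # (k, n_frames) mean normalized trace per cluster
    fits: list[rhythm.RhythmFit]  # per cluster
    com: np.ndarray  # (k, 2) center of mass (row, col), pixels
    inertia: float
    seed: int | None
    roi_centers: np.ndarray  # (n_roi, 2)
    roi_size: int
    frame_interval_h: float

    @property
    def is_nr(self) -> np.ndarray:
        """Per-cluster nonrhythmic flag (NR applied at cluster level)."""
        return np.array([not f.is_rhythmic for f in self.fits])

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class WaveVector:
    """Direction of spatiotemporal phase progression across clusters."""

    angle_rad: float
    r2: float
    path: np.ndarray  # (m, 2) ordered rhythmic-cluster COMs
    defined: bool = True

    @property
    def angle_deg(self) -> float:
        return math.degrees(self.angle_rad)


def kmeans_timeseries(
    rois: RoiSeriesSet,
    k: int = 5,
    seed: int | None = 0,
    n_init: int = 10,
    band_h: tuple[float, float] = rhythm.DEFAULT_BAND_H,
    rae_threshold: float = rhythm.DEFAULT_RAE_THRESHOLD,
    series: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster normalized ROI traces with seeded k-means (Lloyd algorithm).

    ``rois.series`` (or ``series`` if given) must already be normalized
    (z-score) so the distance is dominated by waveform shape and phase. Uses
    k-means++ initialization with ``n_init`` restarts, keeping the best
    inertia; results are deterministic given ``seed``. If the data hold fewer
    distinct traces than ``k``, ``k`` is reduced with a warning.

    Each cluster's mean trace is then fitted with the dominant-sinewave
    model; the per-cluster ``abs_phase_h`` is the peak time used downstream
    (it controls for between-cluster period differences), and clusters whose
    mean-trace fit is nonrhythmic are flagged NR.
    """
    X = rois.series if series is None else np.asarray(series, dtype=np.float64)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} ROIs, got {n}")
    n_unique = np.unique(X, axis=0).shape[0]
    if n_unique < k:
        warnings.warn(
            f"only {n_unique} distinct traces; reducing k from {k} to {n_unique}",
            stacklevel=2,
        )
        k = n_unique
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    labels = km.labels_.astype(np.int64)

    mean_series = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    fits = [
        rhythm.fit_dominant_sinewave(
            mean_series[c], rois.frame_interval_h, band_h, rae_threshold
        )
        for c in range(k)
    ]
    # Center of mass of each cluster on the label image; with uniform square
    # tiles this equals the mean of the member ROI centers.
    label_img = np.zeros(
        (rois.roi_centers[:, 0].max() + 1, rois.roi_centers[:, 1].max() + 1), dtype=np.int64
    )
    label_img[rois.roi_centers[:, 0], rois.roi_centers[:, 1]] = labels + 1
    weights = np.zeros_like(label_img, dtype=float)
    weights[rois.roi_centers[:, 0], rois.roi_centers[:, 1]] = 1.0
    com = np.vstack(
        [ndimage.center_of_mass(weights, label_img, index=c + 1) for c in range(k)]
    )
    return ClusterResult(
        k=k,
        labels=labels,
        mean_series=mean_series,
        fits=fits,
        com=com,
        inertia=float(km.inertia_),
        seed=seed,
        roi_centers=rois.roi_centers,
        roi_size=rois.roi_size,
        frame_interval_h=rois.frame_interval_h,
    )


def cluster_phase_map(
    result: ClusterResult, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Render a per-pixel image of each cluster's peak phase (abs_phase_h).

    Returns ``(phase_img, nr_mask)``: pixels of rhythmic clusters carry their
    cluster's fitted peak time; pixels of NR clusters are NaN in the phase
    image and True in ``nr_mask``; pixels outside any retained ROI are NaN in
    both senses (False in ``nr_mask``).
    """
    shape = tuple(shape)
    if result.roi_centers.size and (
        result.roi_centers[:, 0].max() >= shape[0]
        or result.roi_centers[:, 1].max() >= shape[1]
    ):
        raise ValueError(f"ROI centers exceed requested map shape {shape}")
    phase_img = np.full(shape, np.nan)
    nr_mask = np.zeros(shape, dtype=bool)
    half = result.roi_size // 2
    nr = result.is_nr
    for (r, c), lab in zip(result.roi_centers, result.labels):
        sl = (slice(r - half, r - half + result.roi_size),
              slice(c - half, c - half + result.roi_size))
        if nr[lab]:
            nr_mask[sl] = True
        else:
            phase_img[sl] = result.fits[lab].abs_phase_h
    return phase_img, nr_mask


def _rank_regression(rank: np.ndarray, coord: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 of coordinate vs phase rank; exact-fit degenerate
    cases (zero coordinate variance) count as R^2 = 1."""
    slope, intercept = np.polyfit(rank, coord, 1)
    pred = slope * rank + intercept
    sst = float(np.sum((coord - coord.mean()) ** 2))
    ssr = float(np.sum((coord - pred) ** 2))
    if sst < 1e-12:
        r2 = 1.0 if ssr < 1e-12 else 0.0
    else:
        r2 = 1.0 - ssr / sst
    return float(slope), r2


def wave_vector(result: ClusterResult, use_rank: bool = True) -> WaveVector:
    """Direction of phase progression from cluster centers of mass.

    Rhythmic clusters are ordered by peak time (abs_phase_h); their COM row
    and column coordinates are each regressed on the phase rank (or on the
    raw phase when ``use_rank`` is False). The wave direction is
    ``atan2(row_slope, col_slope)`` — the direction along which peak time
    increases — and ``r2`` the mean R^2 of the two coordinate regressions.

    With fewer than two rhythmic clusters (or coincident COMs) the vector is
    undefined and returned flagged, not raised.
    """
    rhythmic = [i for i in range(result.k) if not result.is_nr[i]]
    if len(rhythmic) < 2:
        return WaveVector(math.nan, math.nan, np.empty((0, 2)), defined=False)
    phases = np.array([result.fits[i].abs_phase_h for i in rhythmic])
    # phase order is unresolvable when all cluster peaks fall within one
    # sampling interval of each other (a synchronous tissue): no wave
    circ = np.sort(np.array([result.fits[i].circ_phase_h for i in rhythmic]))
    gaps = np.diff(np.concatenate([circ, [circ[0] + 24.0]]))
    circ_range = 24.0 - gaps.max()
    if circ_range < result.frame_interval_h:
        return WaveVector(math.nan, math.nan, result.com[rhythmic], defined=False)
    order = np.argsort(phases)
    coms = result.com[np.array(rhythmic)[order]]
    if np.allclose(coms, coms[0]):
        return WaveVector(math.nan, math.nan, coms, defined=False)
    x = np.arange(len(order), dtype=float) if use_rank else phases[order]
    if not use_rank and np.ptp(x) < 1e-12:
        return WaveVector(math.nan, math.nan, coms, defined=False)
    row_slope, row_r2 = _rank_regression(x, coms[:, 0])
    col_slope, col_r2 = _rank_regression(x, coms[:, 1])
    angle = math.atan2(row_slope, col_slope)
    return WaveVector(angle, 0.5 * (row_r2 + col_r2), coms, defined=True)
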