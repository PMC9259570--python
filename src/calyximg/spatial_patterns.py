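"""Per-event spatial activation maps and their clustering.

For each analyzed segment the movie is 2×2 pixel-binned and every pixel
is normalized to %ΔF/F against its own centered 400-frame (20 s) rolling
mean; the global minimum of the normalized video is then subtracted so
all values are non-negative while intensity relationships are preserved.
The spatial pattern of an event is the average of its peak frame ± 1,
normalized to the maximum pixel value inside the ROI, Gaussian-smoothed
(σ = 1 pixel, skippable per animal), and thresholded at 0.5 — patterns
encode relative, not absolute, intensities.  Patterns from all segments
of an animal are clustered with K-means to reveal recurrent spatial
configurations, and stimulus-evoked patterns are assigned to the nearest
spontaneous cluster post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import Movie, ROIMask

__all__ = [
    "SpatialPattern",
    "PatternClustering",
    "bin2x2",
    "pixelwise_dff",
    "extract_pattern",
    "cluster_patterns",
    "assign_stimulus_patterns",
    "DEFAULT_ROLLING_WINDOW_FRAMES",
    "DEFAULT_PATTERN_THRESHOLD",
]

DEFAULT_ROLLING_WINDOW_FRAMES = 400  # 20 s at 20 Hz
DEFAULT_PATTERN_THRESHOLD = 0.5
DEFAULT_GAUSSIAN_SIGMA = 1.0


@dataclass
class SpatialPattern:
    """Normalized activation map at one event/stimulus peak.

    ``map`` covers the (binned) frame with out-of-ROI pixels fixed at 0;
    values lie in [0, 1] and, when any pixel survives thresholding, the
    in-ROI maximum is exactly 1.
    """

    map: np.ndarray
    peak_frame: int
    source: Union[int, str, None] = None

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if self.map.ndim != 2:
            raise ValueError("SpatialPattern.map must be 2-D")


@dataclass
class PatternClustering:
    """K-means result over a pattern set (vectors restricted to the ROI)."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray  # k × n_roi_pixels, row-major ROI order
    inertia: float
    roi_mask: np.ndarray
    member_distances: np.ndarray  # pattern-to-own-centroid Euclidean distances
    silhouette: Optional[float] = None

    def centroid_maps(self) -> List[np.ndarray]:
        maps = []
        for c in self.centroids:
            m = np.zeros(self.roi_mask.shape)
            m[self.roi_mask] = c
            maps.append(m)
        return maps


def _movie_data(movie) -> np.ndarray:
    return np.asarray(movie.data if isinstance(movie, Movie) else movie, dtype=float)


def bin2x2(movie):
    """Spatially bin each frame by averaging 2×2 blocks.

    Odd trailing rows/columns are cropped with a warning.  Accepts a
    :class:`~calyximg.io.Movie` (returns one) or a T×H×W array.
    """
    data = _movie_data(movie)
    t, h, w = data.shape
    if h % 2 or w % 2:
        warnings.warn(
            f"odd frame dimensions {(h, w)}; cropping to {(h - h % 2, w - w % 2)} "
            "before 2×2 binning",
            stacklevel=2,
        )
        data = data[:, : h - h % 2, : w - w % 2]
        h, w = data.shape[1:]
    binned = data.reshape(t, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
    if isinstance(movie, Movie):
        pixel = movie.pixel_size_um * 2 if movie.pixel_size_um else None
        return Movie(binned, movie.frame_rate_hz, pixel)
    return binned


def _centered_rolling_mean(data: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean along axis 0 with shrinking windows at edges."""
    t = data.shape[0]
    half_lo = (window - 1) // 2
    half_hi = window - half_lo  # window = half_lo + half_hi, right-heavy for even
    cum = np.concatenate(
        [np.zeros((1,) + data.shape[1:]), np.cumsum(data, axis=0)], axis=0
    )
    starts = np.clip(np.arange(t) - half_lo, 0, t)
    stops = np.clip(np.arange(t) + half_hi, 0, t)
    sums = cum[stops] - cum[starts]
    counts = (stops - starts).astype(float)
    return sums / counts.reshape((-1,) + (1,) * (data.ndim - 1))


def pixelwise_dff(
    movie, window_frames: int = DEFAULT_ROLLING_WINDOW_FRAMES
) -> np.ndarray:
    """Per-pixel %ΔF/F against a centered rolling-mean baseline.

    After normalization the global minimum over the whole video is
    subtracted, so the output is everywhere >= 0 with an exact minimum of 0.
    """
    data = _movie_data(movie)
    if data.shape[0] < window_frames:
        raise ValueError(
            f"movie has {data.shape[0]} frames but the rolling window needs "
            f"{window_frames}"
        )
    f0 = _centered_rolling_mean(data, window_frames)
    if np.min(f0) <= 0:
        raise ValueError(
            "pixel rolling-mean baseline reached a non-positive value; "
            "%ΔF/F is undefined for dark/empty pixels"
        )
    dff = (data - f0) / f0 * 100.0
    return dff - dff.min()


def extract_pattern(
    normalized_movie,
    peak_frame: int,
    roi,
    sigma: float = DEFAULT_GAUSSIAN_SIGMA,
    threshold: float = DEFAULT_PATTERN_THRESHOLD,
    gaussian_on: bool = True,
    source=None,
) -> SpatialPattern:
    """Activation map at an event peak: mean of peak ± 1 frames, max-normalized
    inside the ROI, optionally Gaussian-smoothed, thresholded at 0.5.

    After smoothing the map is re-normalized to the in-ROI maximum so the
    threshold keeps the same relative meaning and the surviving maximum is 1.
    An all-zero in-ROI neighbourhood yields an all-zero map with a warning.
    """
    data = _movie_data(normalized_movie)
    mask = np.asarray(getattr(roi, "mask", roi), dtype=bool)
    if mask.shape != data.shape[1:]:
        raise ValueError("ROI shape does not match the movie frames")
    if not 1 <= peak_frame <= data.shape[0] - 2:
        raise ValueError(
            f"peak_frame {peak_frame} needs both neighbours inside [0, {data.shape[0]})"
        )
    snap = data[peak_frame - 1 : peak_frame + 2].mean(axis=0)
    snap = np.where(mask, snap, 0.0)
    peak_val = snap[mask].max()
    if peak_val <= 0:
        warnings.warn(
            f"in-ROI maximum at frame {peak_frame} is 0; returning an empty pattern",
            stacklevel=2,
        )
        return SpatialPattern(np.zeros_like(snap), peak_frame, source)
    pattern = snap / peak_val
    if gaussian_on and sigma > 0:
        pattern = gaussian_filter(pattern, sigma)
        pattern = np.where(mask, pattern, 0.0)
        pattern /= pattern[mask].max()
    pattern = np.where(pattern >= threshold, pattern, 0.0)
    return SpatialPattern(pattern, peak_frame, source)


def _pattern_matrix(
    patterns: Sequence[SpatialPattern], roi_mask: np.ndarray
) -> np.ndarray:
    rows = []
    for p in patterns:
        if p.map.shape != roi_mask.shape:
            raise ValueError("all patterns must share the ROI grid")
        rows.append(p.map[roi_mask])  # row-major in-ROI order
    return np.asarray(rows)


def cluster_patterns(
    patterns: Sequence[SpatialPattern],
    roi,
    k: Optional[int] = None,
    k_range: Optional[Sequence[int]] = None,
    seed: int = 0,
    n_init: int = 10,
) -> PatternClustering:
    """K-means over flattened in-ROI pattern vectors.

    Give either ``k`` or ``k_range``; with a range, k is chosen by the
    maximum mean silhouette score (deterministic given the seed).
    """
    mask = np.asarray(getattr(roi, "mask", roi), dtype=bool)
    X = _pattern_matrix(patterns, mask)
    n = X.shape[0]
    if k is None and k_range is None:
        raise ValueError("provide k or k_range")
    if k is not None:
        if n < k:
            raise ValueError(f"{n} patterns cannot support k = {k}")
        best = _fit_kmeans(X, k, seed, n_init)
        sil = None
        if 2 <= k <= n - 1:
            sil = float(silhouette_score(X, best.labels_))
        return _as_clustering(best, X, mask, sil)
    candidates = [kk for kk in k_range if 2 <= kk <= n - 1]
    if not candidates:
        raise ValueError(
            f"k_range {list(k_range)} has no feasible value for {n} patterns"
        )
    scored = []
    for kk in candidates:
        km = _fit_kmeans(X, kk, seed, n_init)
        scored.append((float(silhouette_score(X, km.labels_)), kk, km))
    sil, _, best = max(scored, key=lambda t: (t[0], -t[1]))
    return _as_clustering(best, X, mask, sil)


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


def _as_clustering(
    km: KMeans, X: np.ndarray, mask: np.ndarray, sil: Optional[float]
) -> PatternClustering:
    dists = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
    return PatternClustering(
        k=km.n_clusters,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        roi_mask=mask,
        member_distances=dists,
        silhouette=sil,
    )


def assign_stimulus_patterns(
    stim_patterns: Sequence[SpatialPattern],
    clustering: PatternClustering,
    match_percentile: float = 95.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid assignment of stimulus-evoked patterns.

    Returns ``(cluster ids, match flags)``; a pattern "matches" the
    spontaneous repertoire when its distance to the assigned centroid is
    within the ``match_percentile``-th percentile of that cluster's
    member-to-own-centroid distances.
    """
    if clustering.centroids.size == 0 or len(stim_patterns) == 0:
        raise ValueError("need a fitted clustering and at least one pattern")
    X = _pattern_matrix(stim_patterns, clustering.roi_mask)
    d = np.linalg.norm(X[:, None, :] - clustering.centroids[None, :, :], axis=2)
    labels = d.argmin(axis=1)
    nearest = d[np.arange(len(X)), labels]
    flags = np.zeros(len(X), dtype=bool)
    for i, lab in enumerate(labels):
        members = clustering.member_distances[clustering.labels == lab]
        if members.size == 0:
            flags[i] = False
        else:
            flags[i] = nearest[i] <= np.percentile(members, match_percentile)
    return labels, flags
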