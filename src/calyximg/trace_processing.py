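"""Raw ROI fluorescence -> %ΔF/F traces.

The processing chain is the standard one for slow bulk-loaded calcium
indicators: average the pixels inside the region of interest frame by
frame, band-pass filter the resulting series (0.025–5 Hz) to strip both
bleaching drift and high-frequency shot noise, and express the result as
a percentage change relative to a low-percentile baseline,

    %ΔF/F = (F − F0) / F0 · 100,   F0 = 8th percentile of the segment.

A low percentile is used for F0 because spontaneous transients are
present throughout a recording, so the mean or median would sit inside
the signal rather than under it.

Notes on the filter realization
-------------------------------
The band-pass is a 2nd-order Butterworth applied forward-backward
(zero-phase), so event onsets and peaks are not delayed — the event
detector's timing rules depend on that.  A high-pass at 0.025 Hz removes
the DC component, which would drive F0 to ~0 and make the ratio
meaningless; the pre-filter segment mean is therefore added back after
filtering, keeping the series on the raw intensity scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _signal

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "extract_roi_trace",
    "bandpass_filter",
    "compute_dff",
    "process_trace",
    "DEFAULT_BAND_HZ",
    "DEFAULT_BASELINE_PERCENTILE",
]

DEFAULT_BAND_HZ = (0.025, 5.0)
DEFAULT_BASELINE_PERCENTILE = 8.0


@dataclass
class FluorescenceTrace:
    """Per-frame mean ROI intensity for one recording segment."""

    values: np.ndarray
    frame_rate_hz: float
    segment_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("FluorescenceTrace.values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FluorescenceTrace.values must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("FluorescenceTrace.frame_rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.frame_rate_hz


@dataclass
class DffTrace:
    """%ΔF/F series for one segment, with the baseline it was computed from."""

    values: np.ndarray
    f0: float
    frame_rate_hz: float
    filter_band_hz: tuple = DEFAULT_BAND_HZ
    segment_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DffTrace.values must be finite")
        if self.f0 <= 0:
            raise ValueError("DffTrace.f0 must be > 0")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.frame_rate_hz


def extract_roi_trace(movie, roi_mask, segment=None) -> FluorescenceTrace:
    """Mean in-ROI intensity per frame.

    Parameters
    ----------
    movie
        ``io.Movie`` (or any object with ``data`` T×H×W and ``frame_rate_hz``).
    roi_mask
        ``io.ROIMask`` or a boolean H×W array.
    segment
        Optional ``io.SegmentAnnotation``; when given, only frames in
        ``[start_frame, end_frame)`` are extracted and the label is attached.
    """
    data = np.asarray(movie.data, dtype=float)
    mask = np.asarray(getattr(roi_mask, "mask", roi_mask), dtype=bool)
    if data.ndim != 3:
        raise ValueError("movie data must be T×H×W")
    if mask.shape != data.shape[1:]:
        raise ValueError(
            f"ROI mask shape {mask.shape} does not match frame shape {data.shape[1:]}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    label = None
    if segment is not None:
        if not (0 <= segment.start_frame < segment.end_frame <= data.shape[0]):
            raise ValueError("segment interval lies outside the movie")
        data = data[segment.start_frame : segment.end_frame]
        label = segment.label
    values = data[:, mask].mean(axis=1)
    return FluorescenceTrace(values, float(movie.frame_rate_hz), segment_label=label)


def _butter_sos(low_hz: float, high_hz: float, frame_rate_hz: float):
    return _signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=frame_rate_hz, output="sos"
    )


def bandpass_filter(
    trace,
    frame_rate_hz: Optional[float] = None,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
):
    """Zero-phase 0.025–5 Hz band-pass with DC restoration.

    Accepts a :class:`FluorescenceTrace` (returns one) or a plain array plus
    ``frame_rate_hz`` (returns an array).  The pre-filter mean is added back
    so the output stays on the raw intensity scale (see module docstring).
    """
    if isinstance(trace, FluorescenceTrace):
        out = bandpass_filter(trace.values, trace.frame_rate_hz, low_hz, high_hz)
        return FluorescenceTrace(out, trace.frame_rate_hz, trace.segment_label)
    if frame_rate_hz is None:
        raise TypeError("frame_rate_hz is required when passing a bare array")
    values = np.asarray(trace, dtype=float)
    if not 0 < low_hz < high_hz < frame_rate_hz / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist"
        )
    sos = _butter_sos(low_hz, high_hz, frame_rate_hz)
    # default sosfiltfilt startup padding; shrink (with a warning) for very
    # short segments instead of refusing them
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if values.size <= 3 * padlen:
        warnings.warn(
            f"segment of {values.size} frames is short for the band-pass startup "
            f"({padlen} frames); using reduced reflective padding",
            stacklevel=2,
        )
        padlen = max(values.size // 3 - 1, 0)
    filtered = _signal.sosfiltfilt(sos, values, padtype="even", padlen=padlen)
    return filtered + values.mean()


def compute_dff(
    filtered_trace,
    percentile: float = DEFAULT_BASELINE_PERCENTILE,
    frame_rate_hz: Optional[float] = None,
    filter_band_hz: tuple = DEFAULT_BAND_HZ,
    segment_label: Optional[str] = None,
) -> DffTrace:
    """%ΔF/F against the segment's ``percentile``-th percentile baseline.

    The percentile uses the linear-interpolation definition.  F0 must come
    out positive — on DC-restored physiological traces it always does; a
    non-positive F0 indicates the mean was never added back after filtering.
    """
    if isinstance(filtered_trace, FluorescenceTrace):
        frame_rate_hz = filtered_trace.frame_rate_hz
        segment_label = segment_label or filtered_trace.segment_label
        filtered_trace = filtered_trace.values
    values = np.asarray(filtered_trace, dtype=float)
    if frame_rate_hz is None:
        raise TypeError("frame_rate_hz is required when passing a bare array")
    f0 = float(np.percentile(values, percentile))
    if f0 <= 0:
        raise ValueError(
            f"baseline F0 = {f0:.3g} <= 0; check that DC restoration was applied "
            "before computing %ΔF/F"
        )
    dff = (values - f0) / f0 * 100.0
    return DffTrace(dff, f0, frame_rate_hz, filter_band_hz, segment_label)


def process_trace(
    raw_values,
    frame_rate_hz: float,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    percentile: float = DEFAULT_BASELINE_PERCENTILE,
    segment_label: Optional[str] = None,
) -> DffTrace:
    """Raw intensity series -> band-pass -> %ΔF/F, the canonical chain."""
    filtered = bandpass_filter(raw_values, frame_rate_hz, low_hz, high_hz)
    return compute_dff(
        filtered,
        percentile,
        frame_rate_hz,
        filter_band_hz=(low_hz, high_hz),
        segment_label=segment_label,
    )
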