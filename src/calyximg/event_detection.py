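"""Rule-based calcium-event detection on %ΔF/F traces.

A calcium event is a spontaneous transient: a quick rise to a peak
followed by an exponential-like decay, or a short decay with a new event
superimposed on it.  The acceptance rules applied to every candidate are

* rise time of at least 2 frames (100 ms at 20 Hz) from onset to peak,
* relative amplitude (peak %ΔF/F minus onset %ΔF/F) of at least
  0.02 %ΔF/F *and* at least 0.3 of the animal's pooled %ΔF/F standard
  deviation over all of its analyzed segments,
* the peak is the first peak occurring within 2 s after the onset.

Candidate proposal — the surrogate for by-eye screening
-------------------------------------------------------
The numeric criteria above presuppose that candidates already *look*
like transients; applied to every wiggle of a noisy trace they accept
ordinary noise excursions, because 0.3 of the pooled SD sits well below
the trace's own fluctuation scale.  Candidate proposal therefore plays
the role of the human screener, deterministically:

1. onsets are local minima of a lightly smoothed copy of the trace
   (3-frame moving average) that precede a contiguous rise;
2. the rise, measured on the smoothed trace against the higher of the
   onset value and the trailing 1-s median (so a noise dip cannot
   manufacture amplitude), must reach ``prominence_factor`` times a
   robust noise scale estimated from median absolute first differences
   — an estimator the transients themselves barely perturb;
3. after its peak the smoothed trace must stay above the half-rise level
   for ``min_persist_frames`` frames: transients decay over many frames,
   noise bumps collapse within a couple.

On noiseless traces the noise scale is 0 and the gates pass everything,
so the proposal reduces to plain local-minimum/rise geometry.  Smoothing
and gating are used **only** to propose candidates; amplitudes and peak
positions are always measured on the unsmoothed trace, and the numeric
criteria are applied verbatim afterwards.  Interior local minima during
a decay split superimposed events into separate candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .trace_processing import DffTrace

__all__ = [
    "CalciumEvent",
    "AnimalNoiseScale",
    "EventRate",
    "pooled_sd",
    "amplitude_threshold",
    "robust_noise_sd",
    "detect_candidates",
    "filter_and_measure",
    "detect_events",
    "event_rate",
    "DEFAULT_MIN_AMP_PCT",
    "DEFAULT_SD_FACTOR",
    "DEFAULT_MIN_RISE_FRAMES",
    "DEFAULT_PEAK_WINDOW_S",
    "DEFAULT_PROMINENCE_FACTOR",
    "DEFAULT_MIN_PERSIST_FRAMES",
]

DEFAULT_MIN_AMP_PCT = 0.02
DEFAULT_SD_FACTOR = 0.3
DEFAULT_MIN_RISE_FRAMES = 2
DEFAULT_PEAK_WINDOW_S = 2.0

SMOOTH_FRAMES = 3  # moving-average width used for candidate proposal only
DEFAULT_PROMINENCE_FACTOR = 5.0
DEFAULT_MIN_PERSIST_FRAMES = 4  # 0.2 s at 20 Hz
BASELINE_WINDOW_FRAMES = 21  # trailing ~1-s median for the rise baseline


@dataclass(frozen=True)
class CalciumEvent:
    """One detected transient."""

    onset_frame: int
    peak_frame: int
    amplitude_pct: float
    segment_label: Optional[str] = None

    def onset_s(self, frame_rate_hz: float) -> float:
        return self.onset_frame / frame_rate_hz

    def peak_s(self, frame_rate_hz: float) -> float:
        return self.peak_frame / frame_rate_hz


@dataclass(frozen=True)
class AnimalNoiseScale:
    """Pooled %ΔF/F standard deviation across all segments of one animal."""

    sd_pct: float
    n_samples: int


@dataclass(frozen=True)
class EventRate:
    rate_hz: float
    n_events: int
    duration_s: float


def _values(trace) -> np.ndarray:
    if isinstance(trace, DffTrace):
        return trace.values
    return np.asarray(trace, dtype=float)


def pooled_sd(dff_traces: Iterable) -> AnimalNoiseScale:
    """Population SD of the concatenated %ΔF/F samples of all segments."""
    arrays = [_values(t) for t in dff_traces]
    if not arrays:
        raise ValueError("pooled_sd requires at least one trace")
    pooled = np.concatenate(arrays)
    return AnimalNoiseScale(float(pooled.std(ddof=0)), pooled.size)


def amplitude_threshold(
    animal_sd,
    min_amp_pct: float = DEFAULT_MIN_AMP_PCT,
    sd_factor: float = DEFAULT_SD_FACTOR,
) -> float:
    """max(absolute floor, sd_factor · pooled SD)."""
    sd = animal_sd.sd_pct if isinstance(animal_sd, AnimalNoiseScale) else float(animal_sd)
    if sd < 0:
        raise ValueError("animal_sd must be >= 0")
    return max(min_amp_pct, sd_factor * sd)


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD from the MAD of first differences.

    Sparse transients contribute few large differences, which the median
    ignores, so the estimate tracks the noise floor rather than the trace
    SD even on event-rich segments.  (For i.i.d. Gaussian noise the first
    difference has SD σ√2, hence the normalization.)
    """
    dv = np.diff(np.asarray(values, dtype=float))
    if dv.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(dv - np.median(dv))) / np.sqrt(2.0))


def _forward_fill_sign(sgn: np.ndarray) -> np.ndarray:
    """Replace zeros with the most recent nonzero value (0 until one occurs)."""
    pos = np.where(sgn != 0, np.arange(sgn.size), -1)
    last = np.maximum.accumulate(pos)
    return np.where(last >= 0, sgn[np.clip(last, 0, None)], 0)


def _backward_fill_sign(sgn: np.ndarray) -> np.ndarray:
    return _forward_fill_sign(sgn[::-1])[::-1]


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Onset-style local minima: the foot of every rise.

    Index ``i`` qualifies when the next step rises (``x[i+1] > x[i]``) and
    the last non-flat step before it fell (or there was none), so a flat
    stretch before a rise contributes its *last* frame — the frame a
    human would mark as the event foot."""
    if x.size < 2:
        return np.array([], dtype=int)
    d = np.diff(x)
    sgn = np.sign(d).astype(int)
    left = _forward_fill_sign(sgn)  # sign of the last non-flat step up to i
    prev = np.concatenate([[0], left[:-1]])
    return np.nonzero((sgn > 0) & (prev <= 0))[0]


def _strict_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of ``x`` (plateaus take their first
    frame; the trace must fall after the plateau).  Endpoints never qualify."""
    if x.size < 3:
        return np.array([], dtype=int)
    d = np.diff(x)
    sgn = np.sign(d).astype(int)
    right = _backward_fill_sign(sgn)
    return np.nonzero((sgn[:-1] > 0) & (right[1:] < 0))[0] + 1


def _passes_shape_gates(
    s: np.ndarray,
    onset: int,
    smoothed_peak: int,
    noise_sd: float,
    prominence_factor: float,
    min_persist_frames: int,
) -> bool:
    rise = s[smoothed_peak] - s[onset]
    if rise <= 0:
        return False
    lo = max(0, onset - BASELINE_WINDOW_FRAMES + 1)
    baseline = max(float(np.median(s[lo : onset + 1])), float(s[onset]))
    if s[smoothed_peak] - baseline < prominence_factor * noise_sd:
        return False
    half = s[onset] + 0.5 * rise
    stop = smoothed_peak
    while stop < s.size and s[stop] >= half:
        stop += 1
    return stop - smoothed_peak >= min_persist_frames


def detect_candidates(
    dff_trace,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
    min_persist_frames: int = DEFAULT_MIN_PERSIST_FRAMES,
) -> List[Tuple[int, int]]:
    """Propose candidate events as ``(onset_frame, extent_end_frame)`` pairs.

    Onsets sit at local minima of the 3-frame-smoothed trace that pass the
    shape gates described in the module docstring; each candidate extends
    to the next local minimum (or the trace end), so a new event
    superimposed on a decay starts its own candidate.
    """
    v = _values(dff_trace)
    if v.size < 5:
        raise ValueError("trace too short for candidate detection (need >= 5 frames)")
    s = uniform_filter1d(v, size=SMOOTH_FRAMES, mode="nearest")
    noise_sd = robust_noise_sd(v)
    minima = _local_minima(s)
    maxima_s = _strict_maxima(s)
    candidates = []
    for onset, nxt in zip(minima, np.append(minima[1:], v.size)):
        j = np.searchsorted(maxima_s, onset, side="right")
        if j == maxima_s.size:
            continue
        if _passes_shape_gates(
            s, int(onset), int(maxima_s[j]), noise_sd, prominence_factor,
            min_persist_frames,
        ):
            candidates.append((int(onset), int(nxt)))
    return candidates


def filter_and_measure(
    candidates: Sequence[Tuple[int, int]],
    dff_trace,
    animal_sd,
    frame_rate_hz: Optional[float] = None,
    min_amp_pct: float = DEFAULT_MIN_AMP_PCT,
    sd_factor: float = DEFAULT_SD_FACTOR,
    min_rise_frames: int = DEFAULT_MIN_RISE_FRAMES,
    peak_window_s: float = DEFAULT_PEAK_WINDOW_S,
) -> List[CalciumEvent]:
    """Apply the numeric event criteria to proposed candidates.

    For every candidate onset the peak is the first strict local maximum of
    the raw trace within ``peak_window_s`` after the onset; the candidate
    becomes an event when the rise spans at least ``min_rise_frames`` frames
    and the onset-to-peak amplitude reaches the threshold.  Candidates whose
    peak window would run past the end of the trace are dropped with a
    warning, and candidates resolving to an already-claimed peak are merged
    into the earliest onset.
    """
    v = _values(dff_trace)
    label = dff_trace.segment_label if isinstance(dff_trace, DffTrace) else None
    if frame_rate_hz is None:
        if not isinstance(dff_trace, DffTrace):
            raise TypeError("frame_rate_hz is required when passing a bare array")
        frame_rate_hz = dff_trace.frame_rate_hz
    window = int(round(peak_window_s * frame_rate_hz))
    threshold = amplitude_threshold(animal_sd, min_amp_pct, sd_factor)
    maxima = _strict_maxima(v)
    events: List[CalciumEvent] = []
    claimed_peaks = set()
    n_boundary = 0
    for onset, _extent in candidates:
        # snap the smoothed-trace onset to the raw-trace foot: the lowest raw
        # value within one frame (ties resolved toward the later frame), so
        # rise duration and amplitude are measured from where the raw trace
        # actually turns up
        lo = max(onset - 1, 0)
        hi = min(onset + 1, v.size - 1)
        window_vals = v[lo : hi + 1]
        onset = int(lo + np.flatnonzero(window_vals == window_vals.min())[-1])
        if onset + window >= v.size:
            n_boundary += 1
            continue
        # first strict raw-trace maximum in (onset, onset + window]
        j = np.searchsorted(maxima, onset, side="right")
        if j == maxima.size or maxima[j] > onset + window:
            continue
        peak = int(maxima[j])
        if peak in claimed_peaks:
            continue
        amplitude = float(v[peak] - v[onset])
        if peak - onset >= min_rise_frames and amplitude >= threshold:
            claimed_peaks.add(peak)
            events.append(CalciumEvent(int(onset), peak, amplitude, label))
    if n_boundary:
        warnings.warn(
            f"dropped {n_boundary} candidate(s) whose {peak_window_s:g}-s peak "
            "window crosses the segment end",
            stacklevel=2,
        )
    return events


def detect_events(
    dff_trace,
    animal_sd,
    frame_rate_hz: Optional[float] = None,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
    min_persist_frames: int = DEFAULT_MIN_PERSIST_FRAMES,
    **kwargs,
) -> List[CalciumEvent]:
    """Candidate proposal followed by criterion filtering, in one call."""
    candidates = detect_candidates(dff_trace, prominence_factor, min_persist_frames)
    return filter_and_measure(candidates, dff_trace, animal_sd, frame_rate_hz, **kwargs)


def event_rate(events: Sequence[CalciumEvent], duration_s: float) -> EventRate:
    """Events per second over the analyzed segment."""
    if duration_s <= 0:
        raise ValueError("segment duration must be > 0 to define a rate")
    n = len(events)
    return EventRate(n / duration_s, n, float(duration_s))
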