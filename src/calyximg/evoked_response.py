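"""Stimulus-evoked activity as window summations.

The evoked response of a trial is the plain sum of %ΔF/F over the
stimulus window minus the sum over the immediately preceding window of
equal length: 9 s for the visual danger stimulus (the two movement
cycles fall inside it), 1 s for the mechanical air-puff.  Sums are over
frames (units %·frame) at the fixed frame rate, not time-integrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .io import SegmentAnnotation
from .trace_processing import DffTrace

__all__ = [
    "EvokedResponse",
    "evoked_sum",
    "vds_trial_windows",
    "mec_trial_windows",
    "VDS_WINDOW_S",
    "MEC_WINDOW_S",
]

VDS_WINDOW_S = 9.0
MEC_WINDOW_S = 1.0


@dataclass(frozen=True)
class EvokedResponse:
    """Window sums for one trial; ``delta = sum_stim - sum_basal``."""

    sum_stim: float
    sum_basal: float
    stim_window: Tuple[int, int]  # half-open frame interval
    basal_window: Tuple[int, int]

    @property
    def delta(self) -> float:
        return self.sum_stim - self.sum_basal


def evoked_sum(
    dff_trace,
    stim_onset_frame: int,
    stim_duration_s: float,
    frame_rate_hz: float | None = None,
) -> EvokedResponse:
    """Sum %ΔF/F over ``[onset, onset+w)`` and the preceding ``[onset-w, onset)``."""
    if isinstance(dff_trace, DffTrace):
        values = dff_trace.values
        frame_rate_hz = dff_trace.frame_rate_hz
    else:
        values = np.asarray(dff_trace, dtype=float)
        if frame_rate_hz is None:
            raise TypeError("frame_rate_hz is required when passing a bare array")
    w = int(round(stim_duration_s * frame_rate_hz))
    if w < 1:
        raise ValueError("stimulus window must span at least one frame")
    onset = int(stim_onset_frame)
    if onset - w < 0:
        raise ValueError(
            f"only {onset} pre-stimulus frames available but the basal window "
            f"needs {w}"
        )
    if onset + w > values.size:
        raise ValueError(
            f"stimulus window [{onset}, {onset + w}) runs past the trace "
            f"({values.size} frames)"
        )
    sum_stim = float(values[onset : onset + w].sum())
    sum_basal = float(values[onset - w : onset].sum())
    return EvokedResponse(sum_stim, sum_basal, (onset, onset + w), (onset - w, onset))


def _windows(segment: SegmentAnnotation, expected_label: str, duration_s: float):
    if segment.label != expected_label:
        raise ValueError(f"expected a {expected_label!r} segment, got {segment.label!r}")
    if not segment.stimulus_onsets:
        raise ValueError(f"{expected_label!r} segment carries no stimulus annotation")
    return segment.stimulus_onsets[0] - segment.start_frame, duration_s


def vds_trial_windows(segment: SegmentAnnotation) -> Tuple[int, float]:
    """(stimulus onset frame relative to segment start, 9 s).

    The 9-s window starts at the first movement-cycle onset; the second
    cycle falls inside it.
    """
    return _windows(segment, "vds", VDS_WINDOW_S)


def mec_trial_windows(segment: SegmentAnnotation) -> Tuple[int, float]:
    """(pulse onset frame relative to segment start, 1 s)."""
    return _windows(segment, "mec", MEC_WINDOW_S)
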