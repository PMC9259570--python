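"""Readers/writers for the formats the pipeline touches.

Movies are multi-page 16-bit grayscale TIFF stacks; ROIs are binary
images (TIFF/PNG) or JSON polygon vertex lists; traces, events and
cohort tables are CSV; configuration is YAML.  Frame indices are 0-based
and intervals are half-open ``[start, end)``; times in seconds are
``frame / frame_rate``.

Acquisition metadata (frame rate, pixel size) that plain TIFF tags do
not carry travels in a YAML sidecar file next to the stack
(``<name>.tif`` + ``<name>.tif.yaml``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml

__all__ = [
    "SEGMENT_LABELS",
    "Movie",
    "ROIMask",
    "SegmentAnnotation",
    "read_movie",
    "write_movie",
    "read_roi_mask",
    "write_roi_mask",
    "read_trace_csv",
    "write_trace_csv",
    "read_events_csv",
    "write_events_csv",
    "events_to_frame",
    "read_annotations",
    "write_annotations",
    "read_config_yaml",
    "write_config_yaml",
    "check_gross_motion",
    "DEFAULT_FRAME_RATE_HZ",
]

SEGMENT_LABELS = ("pre", "ctx", "pos", "vds", "posvds", "mec")
DEFAULT_FRAME_RATE_HZ = 20.0
UINT16_MAX = 65535

EVENTS_CSV_COLUMNS = ["animal", "segment", "onset_s", "peak_s", "amplitude_pct"]
TRACE_CSV_COLUMNS = ["frame", "intensity"]


@dataclass
class Movie:
    """A T×H×W grayscale intensity stack on the 16-bit scale."""

    data: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("Movie.data must be T×H×W with T >= 1")
        if np.min(self.data) < 0:
            raise ValueError("Movie.data must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("Movie.frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class ROIMask:
    """Boolean region-of-interest mask over the frame."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROIMask.mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROIMask.mask has no true pixel")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentAnnotation:
    """Labelled half-open frame interval, with stimulus onsets for trials."""

    label: str
    start_frame: int
    end_frame: int
    stimulus_onsets: List[int] = field(default_factory=list)
    stimulus_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(
                f"unknown segment label {self.label!r}; expected one of {SEGMENT_LABELS}"
            )
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError(
                f"segment interval [{self.start_frame}, {self.end_frame}) is invalid"
            )
        self.stimulus_onsets = [int(f) for f in self.stimulus_onsets]
        for f in self.stimulus_onsets:
            if not self.start_frame <= f < self.end_frame:
                raise ValueError(
                    f"stimulus onset frame {f} outside segment "
                    f"[{self.start_frame}, {self.end_frame})"
                )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration_s(self, frame_rate_hz: float) -> float:
        return self.n_frames / frame_rate_hz

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
            "stimulus_onsets": list(self.stimulus_onsets),
            "stimulus_duration_s": self.stimulus_duration_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentAnnotation":
        return cls(
            label=d["label"],
            start_frame=int(d["start_frame"]),
            end_frame=int(d["end_frame"]),
            stimulus_onsets=list(d.get("stimulus_onsets") or []),
            stimulus_duration_s=d.get("stimulus_duration_s"),
        )


# ---------------------------------------------------------------------------
# movies


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".yaml")


def read_movie(path, frame_rate_hz: Optional[float] = None) -> Movie:
    """Read a single- or multi-page grayscale TIFF stack.

    ``frame_rate_hz`` (argument) overrides the YAML sidecar, which overrides
    the 20 Hz default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages (got array of shape {data.shape})"
        )
    pixel_size = None
    meta_rate = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        meta_rate = meta.get("frame_rate_hz")
        pixel_size = meta.get("pixel_size_um")
    rate = frame_rate_hz or meta_rate or DEFAULT_FRAME_RATE_HZ
    return Movie(data, float(rate), pixel_size)


def write_movie(movie: Movie, path) -> None:
    """Write a multi-page 16-bit TIFF plus its metadata sidecar."""
    path = Path(path)
    data = np.asarray(movie.data)
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {"frame_rate_hz": float(movie.frame_rate_hz)}
    if movie.pixel_size_um is not None:
        meta["pixel_size_um"] = float(movie.pixel_size_um)
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


# ---------------------------------------------------------------------------
# ROI masks


def rasterize_polygon(vertices: Sequence[Sequence[float]], shape: tuple) -> np.ndarray:
    """Rasterize a polygon given as (x, y) vertices in pixel coordinates.

    A pixel (row r, column c) has its center at (x=c, y=r) and is in-ROI
    when the center falls inside the polygon; centers on the left/top
    boundary count as inside (half-open convention), implemented by
    nudging test points by +1e-9 in x and y.
    """
    poly = shapely.Polygon([(float(x), float(y)) for x, y in vertices])
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon is degenerate or self-intersecting")
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    eps = 1e-9
    inside = shapely.contains_xy(poly, cols.ravel() + eps, rows.ravel() + eps)
    return inside.reshape(h, w)


def read_roi_mask(path, movie_shape: tuple) -> ROIMask:
    """Read an ROI from a binary image (> 0 is in-ROI) or a JSON polygon.

    JSON format: ``{"vertices": [[x, y], ...]}`` or a bare vertex list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    h, w = movie_shape[-2:]
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        vertices = payload["vertices"] if isinstance(payload, dict) else payload
        mask = rasterize_polygon(vertices, (h, w))
    else:
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:  # collapse identical channels, reject true colour
            if not np.all(img == img[..., :1]):
                raise ValueError(f"{path}: ROI image must be grayscale/binary")
            img = img[..., 0]
        mask = img > 0
    if mask.shape != (h, w):
        raise ValueError(
            f"ROI shape {mask.shape} does not match movie frame shape {(h, w)}"
        )
    if not mask.any():
        raise ValueError(f"{path}: ROI mask is empty")
    return ROIMask(mask)


def write_roi_mask(roi: ROIMask, path) -> None:
    path = Path(path)
    img = roi.mask.astype(np.uint8) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


# ---------------------------------------------------------------------------
# traces and events


def write_trace_csv(values, path, frame_rate_hz: Optional[float] = None) -> None:
    """Persist a raw intensity trace as ``frame,intensity`` CSV."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({"frame": np.arange(values.size), "intensity": values})
    df.to_csv(path, index=False, lineterminator="\n")
    if frame_rate_hz is not None:
        _sidecar_path(path).write_text(
            yaml.safe_dump({"frame_rate_hz": float(frame_rate_hz)})
        )


def read_trace_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trace CSV missing column(s) {missing}")
    return df["intensity"].to_numpy(dtype=float)


def events_to_frame(events: Iterable, animal_id: str, frame_rate_hz: float) -> pd.DataFrame:
    """Tabulate :class:`~calyximg.event_detection.CalciumEvent` objects."""
    rows = [
        {
            "animal": animal_id,
            "segment": ev.segment_label or "",
            "onset_s": ev.onset_frame / frame_rate_hz,
            "peak_s": ev.peak_frame / frame_rate_hz,
            "amplitude_pct": ev.amplitude_pct,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENTS_CSV_COLUMNS)


def write_events_csv(events, path) -> None:
    """Write the fixed-header events table; times in seconds, 3 decimals.

    ``events`` is a DataFrame with the documented columns, or an iterable of
    dicts carrying them.
    """
    if not isinstance(events, pd.DataFrame):
        events = pd.DataFrame(list(events), columns=EVENTS_CSV_COLUMNS)
    missing = [c for c in EVENTS_CSV_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing column(s) {missing}")
    out = events[EVENTS_CSV_COLUMNS].copy()
    for col in ("onset_s", "peak_s"):
        out[col] = out[col].map(lambda v: format(float(v), ".3f"))
    out["amplitude_pct"] = out["amplitude_pct"].map(lambda v: format(float(v), ".6g"))
    out.to_csv(path, index=False, lineterminator="\n")


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENTS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: events CSV missing column(s) {missing}")
    return df[EVENTS_CSV_COLUMNS]


# ---------------------------------------------------------------------------
# annotations and config


def write_annotations(annotations: Sequence[SegmentAnnotation], path) -> None:
    Path(path).write_text(
        json.dumps([a.to_dict() for a in annotations], indent=2) + "\n"
    )


def read_annotations(path) -> List[SegmentAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [SegmentAnnotation.from_dict(d) for d in payload]


def write_config_yaml(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


# ---------------------------------------------------------------------------
# QC


def check_gross_motion(movie: Movie, z_threshold: float = 8.0) -> np.ndarray:
    """Flag frames with a gross frame-to-frame intensity jump.

    Computes the mean absolute difference between consecutive frames and
    flags robust-z outliers.  This is a warning-only QC step — inputs are
    assumed motion-corrected, and segments that cannot be corrected should
    be discarded upstream.
    """
    data = np.asarray(movie.data, dtype=float)
    if data.shape[0] < 3:
        return np.array([], dtype=int)
    mad_series = np.abs(np.diff(data, axis=0)).mean(axis=(1, 2))
    med = np.median(mad_series)
    scale = np.median(np.abs(mad_series - med)) * 1.4826
    if scale == 0:
        return np.array([], dtype=int)
    flagged = np.nonzero((mad_series - med) / scale > z_threshold)[0] + 1
    if flagged.size:
        warnings.warn(
            f"possible gross motion at frame(s) {flagged.tolist()}; "
            "motion correction is out of scope — inspect or discard the segment",
            stacklevel=2,
        )
    return flagged
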