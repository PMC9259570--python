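"""Synthetic calcium recordings with known ground truth.

Emulates the study's recordings so that every pipeline stage can be
verified against planted values: baseline fluorescence with slow
mono-exponential bleaching, i.i.d. Gaussian noise, spontaneous
transients (linear rise over a couple of frames, exponential decay)
arriving as a Poisson process, stimulus-locked transients (two per
visual-danger-stimulus trial — one per panel movement cycle — and one
per mechanical trial), recurrent spatial activation motifs inside the
ROI, and group-level effects: trained (TR) animals get an elevated
post-context event rate and a suppressed vds-evoked response, while
naïve (NAIVE) and cycloheximide-treated (TR_CHX) animals get neither.

Transients multiply the bleached baseline (fractional signal), so a
planted amplitude of ``a`` %ΔF/F survives the downstream ΔF/F
normalization as ``a`` within filter distortion.  Overlapping kernels
superpose additively, producing the "short decay followed by a
superimposed new event" candidate shape.

Default study conditions
------------------------
20 Hz frame rate; 139-s spontaneous segments (the average analyzed
segment length, within the 60–188 s range); a 27-s context with the vds
occupying its last 9 s as two movement cycles separated by 2 s; 6 NAIVE
and 5 TR animals.  Rates and amplitudes are not reported numerically in
the study, so the defaults are realistic free parameters chosen once:
0.10 Hz spontaneous rate, 1.0 %ΔF/F spontaneous amplitude, 0.2 %ΔF/F
noise, +0.12 Hz trained post-context rate increase, 2.0 %ΔF/F evoked
transients with the trained vds response suppressed to 0.2 %ΔF/F (see
docs/methods.md for the power reasoning).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .io import (
    DEFAULT_FRAME_RATE_HZ,
    Movie,
    ROIMask,
    SEGMENT_LABELS,
    SegmentAnnotation,
    UINT16_MAX,
)

__all__ = [
    "GROUP_LABELS",
    "TransientKernel",
    "SimulationConfig",
    "SegmentTruth",
    "AnimalRecording",
    "CohortSim",
    "make_kernel",
    "simulate_trace_segment",
    "simulate_movie",
    "simulate_cohort",
    "expected_evoked_sum",
    "VDS_CONTEXT_S",
    "VDS_WINDOW_S",
]

GROUP_LABELS = ("NAIVE", "TR", "TR_CHX")

# trial geometry: the vds occupies the last 9 s of a 27-s context
# presentation, as two ~2.2-s panel movement cycles separated by 2 s
VDS_CONTEXT_S = 27.0
VDS_WINDOW_S = 9.0
VDS_CYCLE_S = 2.2
VDS_CYCLE_GAP_S = 2.0
MEC_WINDOW_S = 1.0

MAX_SEGMENT_S = 400.0  # continuous recordings last at most 400 s


@dataclass(frozen=True)
class TransientKernel:
    """Shape of one calcium transient: linear rise, exponential decay."""

    rise_frames: int = 2
    decay_tau_s: float = 1.0
    amplitude_pct: float = 1.0
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self) -> None:
        if self.rise_frames < 1:
            raise ValueError("rise_frames must be >= 1")
        if self.decay_tau_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("decay_tau_s and frame_rate_hz must be > 0")
        if self.amplitude_pct < 0:
            raise ValueError("amplitude_pct must be >= 0")

    def sample(self, length_s: Optional[float] = None) -> np.ndarray:
        return make_kernel(
            self.rise_frames,
            self.decay_tau_s,
            self.amplitude_pct,
            self.frame_rate_hz,
            length_s,
        )


def make_kernel(
    rise_frames: int,
    decay_tau_s: float,
    amplitude_pct: float,
    frame_rate_hz: float,
    length_s: Optional[float] = None,
) -> np.ndarray:
    """Sample the transient kernel on the frame grid.

    ``kernel[0] = 0``; the value rises linearly to ``amplitude_pct`` at
    frame ``rise_frames`` and decays as ``amplitude_pct · exp(-t/τ)``
    afterwards.  ``length_s`` must cover at least five decay taus so the
    truncated tail is negligible (default: six).
    """
    if rise_frames < 1:
        raise ValueError("rise_frames must be >= 1")
    if decay_tau_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("decay_tau_s and frame_rate_hz must be > 0")
    if amplitude_pct < 0:
        raise ValueError("amplitude_pct must be >= 0")
    min_length = rise_frames / frame_rate_hz + 5.0 * decay_tau_s
    if length_s is None:
        length_s = rise_frames / frame_rate_hz + 6.0 * decay_tau_s
    elif length_s < min_length:
        raise ValueError(
            f"length_s = {length_s:g} s does not cover five decay taus "
            f"(need >= {min_length:g} s)"
        )
    n = int(round(length_s * frame_rate_hz)) + 1
    i = np.arange(n)
    rise = amplitude_pct * i / rise_frames
    decay = amplitude_pct * np.exp(-(i - rise_frames) / (decay_tau_s * frame_rate_hz))
    return np.where(i <= rise_frames, rise, decay)


def _per_group(value, groups: Sequence[str]) -> Dict[str, float]:
    if isinstance(value, Mapping):
        return {g: float(value.get(g, 0.0)) for g in groups}
    return {g: float(value) for g in groups}


def _default_segment_durations() -> Dict[str, float]:
    return {
        "pre": 139.0,
        "ctx": VDS_CONTEXT_S,
        "pos": 139.0,
        "vds": 30.0,
        "posvds": 139.0,
        "mec": 20.0,
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    segment_durations_s: Dict[str, float] = field(
        default_factory=_default_segment_durations
    )
    segments: Tuple[str, ...] = SEGMENT_LABELS
    spont_rate_hz: float = 0.10
    planted_rate_delta_hz: Dict[str, float] = field(
        default_factory=lambda: {"NAIVE": 0.0, "TR": 0.12, "TR_CHX": 0.0}
    )
    kernel: TransientKernel = field(default_factory=TransientKernel)
    noise_sd_pct: float = 0.2
    bleach_tau_s: float = 600.0
    baseline_intensity: float = 10000.0
    vds_evoked_amplitude_pct: Dict[str, float] = field(
        default_factory=lambda: {"NAIVE": 2.0, "TR": 0.2, "TR_CHX": 2.0}
    )
    mec_evoked_amplitude_pct: Dict[str, float] = field(
        default_factory=lambda: {"NAIVE": 2.0, "TR": 2.0, "TR_CHX": 2.0}
    )
    # spatial parameters (movies only)
    frame_shape: Tuple[int, int] = (32, 32)
    n_motifs: int = 3
    motif_centers: Optional[Tuple[Tuple[float, float], ...]] = None
    motif_sigma_px: float = 1.5
    # cohort design
    group_labels: Tuple[str, ...] = ("NAIVE", "TR")
    n_per_group: Union[int, Dict[str, int]] = field(
        default_factory=lambda: {"NAIVE": 6, "TR": 5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.spont_rate_hz < 0 or self.noise_sd_pct < 0:
            raise ValueError("rates and noise SDs must be >= 0")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be > 0 (use np.inf for no bleaching)")
        if self.baseline_intensity <= 0 or self.baseline_intensity > UINT16_MAX:
            raise ValueError("baseline_intensity must be in (0, 65535]")
        for label, dur in self.segment_durations_s.items():
            if label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {label!r}")
            if not 0 < dur <= MAX_SEGMENT_S:
                raise ValueError(
                    f"segment {label!r} duration {dur:g} s outside (0, {MAX_SEGMENT_S:g}]"
                )
        for label in self.segments:
            if label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {label!r}")
        if "vds" in self.segment_durations_s and self.segment_durations_s[
            "vds"
        ] < VDS_CONTEXT_S:
            raise ValueError(f"vds segment must cover the {VDS_CONTEXT_S:g}-s context")
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        self.planted_rate_delta_hz = _per_group(self.planted_rate_delta_hz, GROUP_LABELS)
        self.vds_evoked_amplitude_pct = _per_group(
            self.vds_evoked_amplitude_pct, GROUP_LABELS
        )
        self.mec_evoked_amplitude_pct = _per_group(
            self.mec_evoked_amplitude_pct, GROUP_LABELS
        )

    def group_sizes(self) -> Dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            sizes = {g: int(self.n_per_group[g]) for g in self.group_labels}
        else:
            sizes = {g: int(self.n_per_group) for g in self.group_labels}
        for g, n in sizes.items():
            if n < 2:
                raise ValueError(
                    f"group {g!r} has n = {n}; at least 2 animals per group are "
                    "needed for the statistics"
                )
        return sizes

    def vds_cycle_onsets_s(self) -> Tuple[float, float]:
        first = VDS_CONTEXT_S - VDS_WINDOW_S
        return (first, first + VDS_CYCLE_S + VDS_CYCLE_GAP_S)

    def mec_onset_s(self) -> float:
        return self.segment_durations_s.get("mec", 20.0) / 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bleach_tau_s"] = (
            None if np.isinf(self.bleach_tau_s) else float(self.bleach_tau_s)
        )
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "kernel" in d and isinstance(d["kernel"], Mapping):
            d["kernel"] = TransientKernel(**d["kernel"])
        if d.get("bleach_tau_s") is None:
            d["bleach_tau_s"] = np.inf
        for key in ("segments", "group_labels", "frame_shape", "motif_centers"):
            if key in d and d[key] is not None:
                d[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in d[key]
                )
        return cls(**d)


@dataclass
class SegmentTruth:
    """Planted ground truth for one simulated segment."""

    label: str
    rate_hz: float
    event_times_s: np.ndarray
    event_motif_ids: Optional[np.ndarray] = None
    evoked_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    evoked_amplitude_pct: float = 0.0


@dataclass
class AnimalRecording:
    """All simulated segments for one animal (trace level)."""

    animal_id: str
    group: str
    traces: Dict[str, np.ndarray]
    annotations: Dict[str, SegmentAnnotation]
    truth: Dict[str, SegmentTruth]


@dataclass
class CohortSim:
    """A simulated multi-animal cohort plus its planted group effects."""

    animals: List[AnimalRecording]
    config: SimulationConfig
    planted_rate_delta_hz: Dict[str, float]
    planted_evoked_delta: Dict[str, float]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _add_kernel(signal: np.ndarray, kernel: np.ndarray, frame: int) -> None:
    stop = min(frame + kernel.size, signal.size)
    if stop > frame >= 0:
        signal[frame:stop] += kernel[: stop - frame]


def _evoked_schedule(config: SimulationConfig, label: str, group: str):
    """(onset times, amplitude) of stimulus-locked transients for a segment."""
    if label == "vds":
        return list(config.vds_cycle_onsets_s()), config.vds_evoked_amplitude_pct[group]
    if label == "mec":
        return [config.mec_onset_s()], config.mec_evoked_amplitude_pct[group]
    return [], 0.0


def _segment_signal_pct(
    config: SimulationConfig, label: str, group: str, rng: np.random.Generator
) -> Tuple[np.ndarray, SegmentTruth]:
    """Noise-free fractional (%ΔF/F) signal plus its ground truth."""
    if label not in SEGMENT_LABELS:
        raise ValueError(f"unknown segment label {label!r}")
    if group not in GROUP_LABELS:
        raise ValueError(f"unknown group label {group!r}")
    fr = config.frame_rate_hz
    duration = config.segment_durations_s[label]
    n = int(round(duration * fr))
    rate = config.spont_rate_hz
    if label == "pos":
        rate += config.planted_rate_delta_hz[group]
    n_events = rng.poisson(rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_events))
    kernel = config.kernel.sample()
    signal = np.zeros(n)
    for t0 in onsets:
        _add_kernel(signal, kernel, int(np.floor(t0 * fr)))
    evoked_times, evoked_amp = _evoked_schedule(config, label, group)
    if evoked_times and evoked_amp > 0:
        ev_kernel = make_kernel(
            config.kernel.rise_frames, config.kernel.decay_tau_s, evoked_amp, fr
        )
        for t0 in evoked_times:
            _add_kernel(signal, ev_kernel, int(np.floor(t0 * fr)))
    truth = SegmentTruth(
        label=label,
        rate_hz=rate,
        event_times_s=onsets,
        evoked_times_s=np.asarray(evoked_times, dtype=float),
        evoked_amplitude_pct=evoked_amp,
    )
    return signal, truth


def _bleach_curve(config: SimulationConfig, n: int) -> np.ndarray:
    t = np.arange(n) / config.frame_rate_hz
    if np.isinf(config.bleach_tau_s):
        return np.ones(n)
    return np.exp(-t / config.bleach_tau_s)


def simulate_trace_segment(
    config: SimulationConfig, segment_label: str, group: str, seed
) -> Tuple[np.ndarray, SegmentTruth]:
    """Simulate one segment's raw ROI-mean intensity series.

    ``series = baseline · exp(-t/τ_bleach) · (1 + Σ kernels/100) + noise``,
    with the Gaussian noise SD expressed as a percentage of the local
    (bleached) baseline so the signal-to-noise ratio is bleach-invariant.
    Values are clipped to the 16-bit range.
    """
    rng = _as_rng(seed)
    signal_pct, truth = _segment_signal_pct(config, segment_label, group, rng)
    n = signal_pct.size
    bleach = config.baseline_intensity * _bleach_curve(config, n)
    raw = bleach * (1.0 + signal_pct / 100.0)
    if config.noise_sd_pct > 0:
        raw = raw + rng.normal(size=n) * bleach * config.noise_sd_pct / 100.0
    return np.clip(raw, 0.0, UINT16_MAX), truth


def _default_roi(shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    rows, cols = np.ogrid[:h, :w]
    return (
        ((rows - (h - 1) / 2) / (0.42 * h)) ** 2
        + ((cols - (w - 1) / 2) / (0.42 * w)) ** 2
    ) <= 1.0


def _default_motif_centers(
    config: SimulationConfig, roi: np.ndarray
) -> List[Tuple[float, float]]:
    h, w = config.frame_shape
    angles = 2 * np.pi * np.arange(config.n_motifs) / config.n_motifs
    centers = []
    for a in angles:
        r = (h - 1) / 2 + 0.22 * h * np.sin(a)
        c = (w - 1) / 2 + 0.22 * w * np.cos(a)
        centers.append((float(r), float(c)))
    return centers


def simulate_movie(
    config: SimulationConfig,
    seed,
    segment_label: str = "pre",
    group: str = "NAIVE",
) -> Tuple[Movie, ROIMask, SegmentTruth]:
    """Simulate a movie in which every event activates one spatial motif.

    Each spontaneous event is assigned a motif (a 2-D Gaussian footprint
    inside the ROI, peak 1 at its center); the event's kernel multiplies
    that footprint over the frames it spans.  Stimulus-locked transients
    activate motif 0.  Outside the ROI, pixels carry only baseline,
    bleaching and noise.
    """
    rng = _as_rng(seed)
    h, w = config.frame_shape
    roi = _default_roi((h, w))
    centers = (
        list(config.motif_centers)
        if config.motif_centers is not None
        else _default_motif_centers(config, roi)
    )
    if len(centers) != config.n_motifs:
        raise ValueError("motif_centers length must equal n_motifs")
    rows, cols = np.ogrid[:h, :w]
    footprints = []
    for r0, c0 in centers:
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError(f"motif center {(r0, c0)} outside frame bounds {(h, w)}")
        if not roi[int(round(r0)), int(round(c0))]:
            raise ValueError(f"motif center {(r0, c0)} outside the ROI")
        fp = np.exp(
            -((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * config.motif_sigma_px**2)
        )
        footprints.append(fp * roi)

    signal_pct, truth = _segment_signal_pct(config, segment_label, group, rng)
    n = signal_pct.size
    fr = config.frame_rate_hz
    kernel = config.kernel.sample()
    motif_ids = rng.integers(0, config.n_motifs, size=truth.event_times_s.size)
    truth.event_motif_ids = motif_ids

    movie_pct = np.zeros((n, h, w))
    for t0, m in zip(truth.event_times_s, motif_ids):
        frame = int(np.floor(t0 * fr))
        stop = min(frame + kernel.size, n)
        if stop > frame >= 0:
            movie_pct[frame:stop] += kernel[: stop - frame, None, None] * footprints[m]
    if truth.evoked_times_s.size and truth.evoked_amplitude_pct > 0:
        ev_kernel = make_kernel(
            config.kernel.rise_frames,
            config.kernel.decay_tau_s,
            truth.evoked_amplitude_pct,
            fr,
        )
        for t0 in truth.evoked_times_s:
            frame = int(np.floor(t0 * fr))
            stop = min(frame + ev_kernel.size, n)
            if stop > frame >= 0:
                movie_pct[frame:stop] += (
                    ev_kernel[: stop - frame, None, None] * footprints[0]
                )

    bleach = config.baseline_intensity * _bleach_curve(config, n)
    data = bleach[:, None, None] * (1.0 + movie_pct / 100.0)
    if config.noise_sd_pct > 0:
        data = data + (
            rng.normal(size=(n, h, w))
            * bleach[:, None, None]
            * config.noise_sd_pct
            / 100.0
        )
    data = np.clip(np.round(data), 0, UINT16_MAX).astype(np.uint16)
    movie = Movie(data, fr, pixel_size_um=2.3)
    return movie, ROIMask(roi), truth


def _annotation_for(config: SimulationConfig, label: str) -> SegmentAnnotation:
    fr = config.frame_rate_hz
    n = int(round(config.segment_durations_s[label] * fr))
    onsets: List[int] = []
    duration = None
    if label == "vds":
        onsets = [int(round(t * fr)) for t in config.vds_cycle_onsets_s()]
        duration = VDS_WINDOW_S
    elif label == "mec":
        onsets = [int(round(config.mec_onset_s() * fr))]
        duration = MEC_WINDOW_S
    return SegmentAnnotation(label, 0, n, onsets, duration)


def expected_evoked_sum(config: SimulationConfig, group: str, stimulus: str) -> float:
    """Planted (noise-free) stimulus-window %ΔF/F sum minus basal sum.

    Units are %·frame, matching the evoked-response module.
    """
    fr = config.frame_rate_hz
    if stimulus == "vds":
        amp = config.vds_evoked_amplitude_pct[group]
        window = int(round(VDS_WINDOW_S * fr))
        first = config.vds_cycle_onsets_s()[0]
        offsets = [t - first for t in config.vds_cycle_onsets_s()]
    elif stimulus == "mec":
        amp = config.mec_evoked_amplitude_pct[group]
        window = int(round(MEC_WINDOW_S * fr))
        offsets = [0.0]
    else:
        raise ValueError(f"unknown stimulus {stimulus!r}")
    if amp == 0:
        return 0.0
    kernel = make_kernel(config.kernel.rise_frames, config.kernel.decay_tau_s, amp, fr)
    total = 0.0
    for off in offsets:
        start = int(np.floor(off * fr))
        stop = min(window, start + kernel.size)
        total += kernel[: stop - start].sum()
    return float(total)


def simulate_cohort(config: SimulationConfig, seed=None) -> CohortSim:
    """Simulate every animal of every group, deterministically from the seed.

    Per-animal random streams are spawned from one seed sequence, so the
    cohort is byte-identical on rerun and unaffected by the order in which
    segments are consumed downstream.
    """
    if seed is None:
        seed = config.seed
    sizes = config.group_sizes()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(sum(sizes.values()))
    animals: List[AnimalRecording] = []
    i = 0
    for group in config.group_labels:
        for k in range(sizes[group]):
            rng = np.random.default_rng(children[i])
            i += 1
            traces, annotations, truths = {}, {}, {}
            for label in config.segments:
                trace, truth = simulate_trace_segment(config, label, group, rng)
                traces[label] = trace
                annotations[label] = _annotation_for(config, label)
                truths[label] = truth
            animals.append(
                AnimalRecording(f"{group}-{k + 1:02d}", group, traces, annotations, truths)
            )
    evoked_delta = {
        g: expected_evoked_sum(config, g, "vds") for g in config.group_labels
    }
    return CohortSim(
        animals,
        config,
        {g: config.planted_rate_delta_hz[g] for g in config.group_labels},
        evoked_delta,
    )
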