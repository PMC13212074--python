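"""Domain types for the walking-task fNIRS analysis.

The measurement model: a 48-channel continuous-wave fNIRS montage
(24 sources, 16 detectors, 3 cm separation) samples dual-wavelength
(730/850 nm) light intensity at 11 Hz while the subject performs a
stand / freezing-induction walk / rest / normal walk / stand protocol.
Channels are grouped into five cortical regions of interest (prefrontal,
premotor, primary motor, primary somatosensory, temporal); nine channels
fall outside any ROI and are retained only for channel-level analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ROI_CHANNELS",
    "ROI_NAMES",
    "N_CHANNELS",
    "ChannelDef",
    "Montage",
    "Paradigm",
    "RawIntensityRecording",
    "HbSeries",
    "GaitRecord",
    "build_default_montage",
    "default_paradigm",
]

N_CHANNELS = 48
N_SOURCES = 24
N_DETECTORS = 16

#: ROI membership of the montage, by 1-based channel id.
ROI_CHANNELS: dict[str, tuple[int, ...]] = {
    "PFC": (4, 6, 7, 8, 9, 10, 11, 12, 22, 23, 24, 25, 26, 27),
    "PMC": (19, 30, 34, 35, 36, 41, 42, 43),
    "M1": (37, 44),
    "S1": (31, 32, 33, 39, 40),
    "TLC": (1, 2, 3, 5, 13, 15, 16, 17, 18, 29),
}
ROI_NAMES = tuple(ROI_CHANNELS)  # ("PFC", "PMC", "M1", "S1", "TLC")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class ChannelDef:
    """One source-detector pair. ``id`` is the 1-based channel number."""

    id: int
    source_id: int
    detector_id: int
    roi: str = "NONE"


@dataclass(frozen=True)
class Montage:
    n_sources: int
    n_detectors: int
    channels: tuple[ChannelDef, ...]
    roi_map: dict[str, tuple[int, ...]]
    separation_cm: float = 3.0
    source_pos: tuple[tuple[float, float, float], ...] = ()
    detector_pos: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(self.channels) != N_CHANNELS:
            raise ValidationError(f"montage must have {N_CHANNELS} channels, got {len(self.channels)}")
        if sorted(ids) != list(range(1, N_CHANNELS + 1)):
            raise ValidationError("channel ids must be exactly 1..48 and unique")
        all_roi_ids: list[int] = []
        for roi, members in self.roi_map.items():
            if not set(members) <= set(ids):
                raise ValidationError(f"ROI {roi} references unknown channel ids")
            all_roi_ids.extend(members)
        if len(all_roi_ids) != len(set(all_roi_ids)):
            raise ValidationError("ROI channel lists must be pairwise disjoint")
        if len(all_roi_ids) != 39:
            raise ValidationError(f"expected 39 ROI-labelled channels, got {len(all_roi_ids)}")
        for ch in self.channels:
            expected = next((r for r, m in self.roi_map.items() if ch.id in m), "NONE")
            if ch.roi != expected:
                raise ValidationError(f"channel {ch.id}: roi {ch.roi!r} inconsistent with roi_map ({expected!r})")

    def roi_of(self, channel_id: int) -> str:
        """ROI label of a 1-based channel id ('NONE' if unassigned)."""
        return self.channels[self.index_of(channel_id)].roi

    def index_of(self, channel_id: int) -> int:
        """0-based array index of a 1-based channel id."""
        if not 1 <= channel_id <= N_CHANNELS:
            raise KeyError(f"channel id {channel_id} out of range 1..{N_CHANNELS}")
        return channel_id - 1

    def roi_indices(self, roi: str) -> np.ndarray:
        """0-based array indices of a ROI's member channels."""
        return np.array([self.index_of(c) for c in self.roi_map[roi]], dtype=int)

    @property
    def unassigned(self) -> tuple[int, ...]:
        assigned = {c for m in self.roi_map.values() for c in m}
        return tuple(i for i in range(1, N_CHANNELS + 1) if i not in assigned)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        d = json.loads(text)
        d["channels"] = tuple(ChannelDef(**c) for c in d["channels"])
        d["roi_map"] = {k: tuple(v) for k, v in d["roi_map"].items()}
        d["source_pos"] = tuple(tuple(p) for p in d["source_pos"])
        d["detector_pos"] = tuple(tuple(p) for p in d["detector_pos"])
        return cls(**d)


def build_default_montage() -> Montage:
    """The study montage: 48 channels, 24 sources, 16 detectors, 3 cm pairs.

    ROI membership follows the published channel lists; 9 channels carry no
    ROI label. Source/detector identities and grid positions are synthesized
    metadata (the optode geometry is never used in any computation).
    """
    channels = []
    for cid in range(1, N_CHANNELS + 1):
        roi = next((r for r, m in ROI_CHANNELS.items() if cid in m), "NONE")
        channels.append(
            ChannelDef(id=cid, source_id=(cid - 1) // 2 + 1, detector_id=(cid - 1) % N_DETECTORS + 1, roi=roi)
        )
    sep = 3.0
    src = tuple((sep * (k % 6), sep * (k // 6), 0.0) for k in range(N_SOURCES))
    det = tuple((sep * (k % 4) + sep / 2, sep * (k // 4) + sep / 2, 0.0) for k in range(N_DETECTORS))
    return Montage(
        n_sources=N_SOURCES,
        n_detectors=N_DETECTORS,
        channels=tuple(channels),
        roi_map=dict(ROI_CHANNELS),
        separation_cm=sep,
        source_pos=src,
        detector_pos=det,
    )


# ---------------------------------------------------------------------------
# Task paradigm
# ---------------------------------------------------------------------------

#: Conditions analysed downstream (keys of Paradigm.analysis_windows).
CONDITIONS = ("rest", "freeze_walk", "normal_walk")


@dataclass(frozen=True)
class Paradigm:
    """Block timing of the walking protocol.

    t = 0 is the onset of the first standing block (the 10-s preparatory
    period is excluded from the recording clock). Windows are half-open
    ``[start, end)`` seconds; sample index = floor(t * fs).
    """

    blocks: tuple[tuple[str, float, float], ...] = (
        ("stand", 0.0, 60.0),
        ("freeze_walk", 60.0, 120.0),
        ("rest", 120.0, 150.0),
        ("normal_walk", 150.0, 210.0),
        ("stand", 210.0, 270.0),
    )
    analysis_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "rest": (0.0, 60.0),
            "freeze_walk": (62.5, 120.0),
            "normal_walk": (152.5, 210.0),
        }
    )
    baseline_window_s: float = 5.0
    task_extract_window: tuple[float, float] = (3.0, 60.0)

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.blocks:
            if end <= start:
                raise ValidationError(f"block {label!r}: end must exceed start")
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"block {label!r} overlaps the previous block")
            prev_end = end
        dur = self.duration
        for cond, (start, end) in self.analysis_windows.items():
            if not (0 <= start < end <= dur):
                raise ValidationError(f"analysis window {cond!r} ({start}, {end}) outside recording [0, {dur}]")

    @property
    def duration(self) -> float:
        return self.blocks[-1][2]

    def walk_onset(self, condition: str) -> float:
        """Block-boundary onset of a walking condition (60 s / 150 s)."""
        for label, start, _ in self.blocks:
            if label == condition:
                return start
        raise KeyError(f"no block labelled {condition!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Paradigm":
        d = json.loads(text)
        d["blocks"] = tuple((b[0], float(b[1]), float(b[2])) for b in d["blocks"])
        d["analysis_windows"] = {k: (float(v[0]), float(v[1])) for k, v in d["analysis_windows"].items()}
        d["task_extract_window"] = tuple(d["task_extract_window"])
        return cls(**d)


def default_paradigm() -> Paradigm:
    return Paradigm()


# ---------------------------------------------------------------------------
# Recordings and derived series
# ---------------------------------------------------------------------------

GROUPS = ("HC", "PD_FOG")
WAVELENGTHS = (730.0, 850.0)
CHROMOPHORES = ("HbO2", "HHb")
FS_DEFAULT = 11.0


@dataclass
class RawIntensityRecording:
    """Raw detected light intensity, shape (48 channels, 2 wavelengths, T)."""

    subject_id: str
    group: str
    fs: float
    data: np.ndarray
    wavelengths: tuple[float, float] = WAVELENGTHS
    paradigm: Paradigm = field(default_factory=default_paradigm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 3 or self.data.shape[:2] != (N_CHANNELS, 2):
            raise ValidationError(f"intensity data must have shape (48, 2, T), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)) or np.any(self.data <= 0):
            bad = np.argwhere(~(np.isfinite(self.data) & (self.data > 0)))[0]
            raise ValidationError(
                f"intensities must be finite and > 0 (first offender: channel {bad[0] + 1}, "
                f"wavelength index {bad[1]}, sample {bad[2]})"
            )
        if self.n_samples < self.paradigm.duration * self.fs:
            raise ValidationError(
                f"recording too short: {self.n_samples} samples < paradigm end "
                f"{self.paradigm.duration} s at {self.fs} Hz"
            )
        if self.fs <= 2 * 0.2:
            raise ValidationError("sampling rate must exceed twice the upper filter cutoff (0.2 Hz)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class HbSeries:
    """Hemoglobin concentration changes in umol/L, shape (48, 2, T).

    Chromophore axis order is (HbO2, HHb). ``qc_mask`` marks retained
    channels; ``artifact_mask`` marks motion-flagged samples per channel.
    """

    data: np.ndarray
    fs: float
    qc_mask: np.ndarray
    artifact_mask: np.ndarray | None = None
    subject_id: str = ""
    group: str = ""
    paradigm: Paradigm = field(default_factory=default_paradigm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[:2] != (N_CHANNELS, 2):
            raise ValidationError(f"Hb data must have shape (48, 2, T), got {self.data.shape}")
        if self.qc_mask.shape != (N_CHANNELS,):
            raise ValidationError("qc_mask must have one flag per channel")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros((N_CHANNELS, self.data.shape[2]), dtype=bool)

    @property
    def hbo(self) -> np.ndarray:
        """HbO2 series, shape (48, T), NaN for QC-excluded channels."""
        out = self.data[:, 0, :].copy()
        out[~self.qc_mask] = np.nan
        return out

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


GAIT_PARAMETERS = ("cadence", "stride_length", "velocity", "swing_width", "foot_progression_angle")
INTERVENTIONS = ("NONE", "RAS_B", "RAS_M", "RAS_I")


@dataclass(frozen=True)
class GaitRecord:
    """Summary gait parameters for one subject under one walking condition."""

    subject_id: str
    group: str
    condition: str  # freeze_induction | normal_walk
    intervention: str  # NONE | RAS_B | RAS_M | RAS_I
    cadence: float  # steps/min
    stride_length: float  # m
    velocity: float  # m/s
    swing_width: float  # cm
    foot_progression_angle: float  # deg
    fog_count: int  # freezing episodes

    def __post_init__(self) -> None:
        if self.condition not in ("freeze_induction", "normal_walk"):
            raise ValidationError(f"unknown gait condition {self.condition!r}")
        if self.intervention not in INTERVENTIONS:
            raise ValidationError(f"unknown intervention {self.intervention!r}")
        for p in GAIT_PARAMETERS:
            if getattr(self, p) < 0:
                raise ValidationError(f"gait parameter {p} must be non-negative")
        if self.fog_count < 0 or int(self.fog_count) != self.fog_count:
            raise ValidationError("fog_count must be a non-negative integer")


def window_slice(window: tuple[float, float], fs: float) -> slice:
    """Half-open time window [start, end) seconds -> sample slice.

    Selects exactly the samples k whose time k/fs lies in [start, end):
    k from ceil(start*fs) to ceil(end*fs) - 1 (tiny epsilon guards float
    fuzz), so e.g. [62.5, 120) at 11 Hz yields 632 samples.
    """
    start, end = window
    return slice(int(np.ceil(start * fs - 1e-9)), int(np.ceil(end * fs - 1e-9)))
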