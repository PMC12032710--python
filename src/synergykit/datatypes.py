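"""Shared data containers for the synergy pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

N_TIME = 101  # time-normalized samples per movement cycle (0..100 %)

SUPPORTS = ("UA", "LT", "FS")
FLOORS = ("non_challenging", "challenging")
MOVEMENTS = ("sit_to_stand", "stand_to_sit")

PRE_WINDOW_S = 0.2  # EMG included before detected movement start (seconds)


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one movement trial."""

    participant: int
    movement: str
    floor: str
    support: str
    repetition: int
    strategy: str

    def __post_init__(self):
        if self.support not in SUPPORTS:
            raise ValueError(f"support must be one of {SUPPORTS}, got {self.support!r}")
        if self.floor not in FLOORS:
            raise ValueError(f"floor must be one of {FLOORS}, got {self.floor!r}")
        if self.movement not in MOVEMENTS:
            raise ValueError(
                f"movement must be one of {MOVEMENTS}, got {self.movement!r}"
            )

    @property
    def task(self) -> str:
        """movement x floor identifier (matching happens within a task)."""
        return f"{self.movement}|{self.floor}"

    @property
    def dataset_label(self) -> str:
        """movement x floor x strategy identifier (one NMF dataset)."""
        return f"{self.movement}|{self.floor}|{self.strategy}"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EventTimes:
    """Movement events on the recording's wall clock, in seconds."""

    movement_start: float
    seat_transition: float
    movement_end: float
    pre_window: float = PRE_WINDOW_S

    def __post_init__(self):
        if not (self.movement_start < self.seat_transition < self.movement_end):
            raise ValueError(
                "events must be ordered start < seat transition < end, got "
                f"({self.movement_start}, {self.seat_transition}, {self.movement_end})"
            )
        if abs(self.pre_window - PRE_WINDOW_S) > 1e-12:
            raise ValueError(f"pre_window is fixed at {PRE_WINDOW_S} s")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Series:
    """A uniformly sampled signal with its own rate."""

    values: np.ndarray
    rate: float  # Hz

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.rate

    @property
    def duration(self) -> float:
        return self.values.shape[0] / self.rate


@dataclass
class RawTrialRecording:
    """Raw multi-channel EMG plus kinetic/kinematic traces, pre-segmentation."""

    emg: list[Series]  # 30 channels, possibly two rate groups
    grf_vertical: Series
    seat_force: Series
    com_vertical: Series
    meta: TrialMeta
    truth: Optional[dict] = None  # generator-only: true events / weightings / envelope
    corrupt_channels: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.emg) != 30:
            raise ValueError(f"expected 30 EMG channels, got {len(self.emg)}")


@dataclass
class ProcessedTrial:
    """101 x 30 nonnegative envelope matrix with events and metadata."""

    envelope: np.ndarray
    events: Optional[EventTimes]
    meta: TrialMeta
    normalization_factors: Optional[np.ndarray] = None
    truth: Optional[dict] = None

    def __post_init__(self):
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.envelope.shape != (N_TIME, 30):
            raise ValueError(
                f"envelope must be {N_TIME}x30, got {self.envelope.shape}"
            )
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be elementwise nonnegative")
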