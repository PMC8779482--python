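"""Core data containers shared across the pipeline.

All signal amplitudes are in microvolts (µV), all times in seconds and all
onsets in 0-based sample indices of the recording they belong to.  Epochs are
1-s windows taken from game/rest onsets, half-open ``[onset, onset + window)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Default 16-channel montage following the international 10–20 system.
CHANNELS_1020_16 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8", "P3", "Pz", "P4", "Oz",
)

#: Frontal / prefrontal electrodes used for condition-level workload analysis.
FRONTAL_CHANNELS = ("Fp1", "F7", "Fp2", "F8", "F3", "F4")

#: Single electrode carrying the regression analyses (strongest load effect).
REGRESSION_CHANNEL = "F4"

REST = "rest"
PICKING = "picking"
COORDINATION = "coordination"
CONDITIONS = (REST, PICKING, COORDINATION)

BAND_NAMES = ("delta", "theta", "alpha", "beta")


class TacitloadError(Exception):
    """Base class for all package errors."""


class ParameterError(TacitloadError, ValueError):
    """Invalid parameter or configuration value."""


class InputError(TacitloadError, ValueError):
    """Malformed input data (wrong shape, non-finite values, missing cells)."""


@dataclass(frozen=True)
class Event:
    """A marker in a continuous recording.

    ``game`` and ``response_time`` are ``None`` for resting-state markers.
    """

    onset: int
    condition: str
    game: int | None = None
    response_time: float | None = None


@dataclass
class RawRecording:
    """Continuous multi-channel EEG with event markers.

    ``signal`` has shape ``(n_channels, n_samples)`` in µV.  Invariants:
    events are sorted by onset and every onset leaves room for a 1-s epoch.
    """

    channels: Sequence[str]
    rate: float
    signal: np.ndarray
    events: list[Event] = field(default_factory=list)
    subject: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channels = list(self.channels)
        if self.rate <= 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise InputError(
                f"signal shape {self.signal.shape} does not match "
                f"{len(self.channels)} channels"
            )
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise InputError("events must be sorted by onset")
        window = int(round(self.rate))
        for e in self.events:
            if e.onset < 0 or e.onset + window > self.n_samples:
                raise InputError(
                    f"event at sample {e.onset} does not leave room for a "
                    f"1-s window in a {self.n_samples}-sample recording"
                )
            if e.condition not in CONDITIONS:
                raise InputError(f"unknown condition {e.condition!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def copy(self) -> "RawRecording":
        return replace(self, signal=self.signal.copy(), events=list(self.events))

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise InputError(f"channel {name!r} not in montage {self.channels}")


@dataclass
class EpochSet:
    """Fixed-length epochs: ``data`` is ``(n_epochs, n_channels, n_samples)``.

    ``meta`` has one row per epoch with columns
    ``subject, condition, game, response_time``.
    """

    data: np.ndarray
    rate: float
    channels: Sequence[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise InputError(f"epoch tensor must be 3-d, got {self.data.ndim}-d")
        if self.data.shape[1] != len(self.channels):
            raise InputError("channel axis does not match channel names")
        if len(self.meta) != self.data.shape[0]:
            raise InputError("meta rows must match number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class ChoiceTable:
    """Subject × game choice matrix for one condition.

    ``choices[s, g]`` is the 0-based label index selected by subject ``s`` in
    game ``g``; ``response_time[s, g]`` is in seconds and strictly positive.
    """

    choices: np.ndarray
    response_time: np.ndarray
    condition: str
    n_labels: int

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.response_time = np.asarray(self.response_time, dtype=float)
        if self.choices.ndim != 2:
            raise InputError("choices must be a 2-d subject × game matrix")
        if self.choices.shape != self.response_time.shape:
            raise InputError("choices and response_time shapes differ")
        if self.condition not in (PICKING, COORDINATION):
            raise InputError(f"condition must be picking/coordination, got {self.condition!r}")
        if self.n_labels < 2:
            raise ParameterError("need at least two labels")
        if self.choices.min(initial=0) < 0 or self.choices.max(initial=0) >= self.n_labels:
            raise InputError("label index outside [0, n_labels)")
        if not np.all(np.isfinite(self.response_time)) or np.any(self.response_time <= 0):
            raise InputError("response times must be finite and > 0")

    @property
    def n_subjects(self) -> int:
        return self.choices.shape[0]

    @property
    def n_games(self) -> int:
        return self.choices.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: subject, game, label, rt_s, condition."""
        s, g = np.indices(self.choices.shape)
        return pd.DataFrame(
            {
                "subject": s.ravel(),
                "game": g.ravel() + 1,
                "label": self.choices.ravel(),
                "rt_s": self.response_time.ravel(),
                "condition": self.condition,
            }
        )
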