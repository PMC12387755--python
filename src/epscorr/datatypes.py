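"""Core domain types for paired spontaneous-EPSC analysis.

All times are in seconds and all amplitudes in picoamperes throughout the
package; file columns carry explicit unit suffixes (``_s``, ``_pA``) so no
implicit conversions happen anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class Label(str, Enum):
    """Activity-dependent reporter status of a recorded neuron."""

    LABELED = "labeled"
    UNLABELED = "unlabeled"


class PairClass(str, Enum):
    """Label composition of a simultaneously recorded cell pair."""

    LL = "LL"  #: both cells labeled
    LU = "LU"  #: exactly one cell labeled
    UU = "UU"  #: neither cell labeled (read but excluded from group analyses)


class ValidationError(ValueError):
    """Raised when an input table or object violates a structural invariant."""


@dataclass(frozen=True)
class EventTrain:
    """Sorted spontaneous-EPSC event times of one cell over a known duration.

    Parameters
    ----------
    cell_id : str
        Unique identifier of the recorded cell.
    label : Label
        Reporter status (labeled/unlabeled).
    duration : float
        Recording duration in seconds, > 0.
    event_times : ndarray of float
        Event times in seconds, nondecreasing, all within [0, duration].
    amplitudes : ndarray of float, optional
        Event amplitudes in pA (> 0), aligned with ``event_times``.
    """

    cell_id: str
    label: Label
    duration: float
    event_times: np.ndarray
    amplitudes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if self.duration <= 0:
            raise ValidationError(
                f"cell {self.cell_id}: duration must be > 0, got {self.duration}"
            )
        if times.ndim != 1:
            raise ValidationError(f"cell {self.cell_id}: event_times must be 1-D")
        if times.size and np.any(np.diff(times) < 0):
            raise ValidationError(f"cell {self.cell_id}: event_times must be sorted")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            bad = int(np.argmax((times < 0) | (times > self.duration)))
            raise ValidationError(
                f"cell {self.cell_id}: event {bad} at t={times[bad]} s outside "
                f"[0, {self.duration}] s"
            )
        if self.amplitudes is not None:
            amps = np.asarray(self.amplitudes, dtype=float)
            object.__setattr__(self, "amplitudes", amps)
            if amps.shape != times.shape:
                raise ValidationError(
                    f"cell {self.cell_id}: amplitudes length {amps.size} != "
                    f"event count {times.size}"
                )
            if amps.size and np.any(amps <= 0):
                raise ValidationError(f"cell {self.cell_id}: amplitudes must be > 0")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def rate(self) -> float:
        """Mean event rate in Hz."""
        return self.n_events / self.duration


def _derive_pair_class(a: Label, b: Label) -> PairClass:
    n_labeled = (a is Label.LABELED) + (b is Label.LABELED)
    return (PairClass.UU, PairClass.LU, PairClass.LL)[n_labeled]


@dataclass(frozen=True)
class PairedSession:
    """Two simultaneously recorded event trains and their pair class."""

    session_id: str
    train_a: EventTrain
    train_b: EventTrain
    pair_class: PairClass = field(init=False)

    def __post_init__(self) -> None:
        if self.train_a.duration != self.train_b.duration:
            raise ValidationError(
                f"session {self.session_id}: trains have different durations "
                f"({self.train_a.duration} vs {self.train_b.duration} s)"
            )
        object.__setattr__(
            self, "pair_class", _derive_pair_class(self.train_a.label, self.train_b.label)
        )

    @property
    def duration(self) -> float:
        return self.train_a.duration


@dataclass(frozen=True)
class Sweep:
    """One current-clamp sweep: uniformly sampled voltage plus step metadata.

    ``voltage`` is in mV on a uniform time base at ``sampling_rate`` Hz;
    ``current`` is the injected step amplitude in pA applied over
    [``pulse_onset``, ``pulse_offset``] seconds.
    """

    voltage: np.ndarray
    sampling_rate: float
    current: float
    pulse_onset: float
    pulse_offset: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "voltage", v)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if not (0 <= self.pulse_onset < self.pulse_offset <= v.size / self.sampling_rate):
            raise ValidationError("current pulse must lie within the trace")

    @property
    def time(self) -> np.ndarray:
        """Time base in seconds."""
        return np.arange(self.voltage.size) / self.sampling_rate

    @property
    def pulse_duration(self) -> float:
        return self.pulse_offset - self.pulse_onset


def as_sessions(trains: Sequence[EventTrain], session_id: str) -> PairedSession:
    """Build a :class:`PairedSession` from exactly two trains."""
    if len(trains) != 2:
        raise ValidationError(
            f"session {session_id}: expected exactly 2 cells, got {len(trains)}"
        )
    return PairedSession(session_id=session_id, train_a=trains[0], train_b=trains[1])
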