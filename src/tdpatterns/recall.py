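"""Eating-event representation of 24-hour dietary recalls.

A recall day is an ordered list of eating occasions, each a clock time
(minute of day) and an energy amount (kcal).  Because recall instruments
do not record occasion duration, every occasion is modelled as lasting
15 minutes: when a recall is expanded to a 1440-minute energy series,
each occasion deposits ``energy / 15`` kcal into each of the 15 minutes
starting at its reported time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
OCCASION_MINUTES = 15

__all__ = [
    "EatingEvent",
    "RecallDay",
    "merge_simultaneous_events",
    "events_to_minute_series",
    "read_events_csv",
    "recalls_from_events",
    "events_frame",
]


@dataclass(frozen=True, order=True)
class EatingEvent:
    """One eating occasion: minute of day in [0, 1440) and energy in kcal (> 0)."""

    time_min: int
    energy_kcal: float

    def __post_init__(self) -> None:
        if not 0 <= self.time_min < MINUTES_PER_DAY:
            raise ValueError(f"time_min {self.time_min} outside [0, {MINUTES_PER_DAY})")
        if not self.energy_kcal > 0:
            raise ValueError(f"energy_kcal must be positive, got {self.energy_kcal}")


def _as_events(events: Iterable) -> list[EatingEvent]:
    out = []
    for ev in events:
        if isinstance(ev, EatingEvent):
            out.append(ev)
        else:
            t, e = ev
            out.append(EatingEvent(int(t), float(e)))
    return out


def merge_simultaneous_events(events: Iterable) -> list[EatingEvent]:
    """Merge occasions reported at the same minute by summing their energy.

    Recall instruments report one row per food, so several items share a
    clock time; the analysis reasons about *eating events*, one per time.
    The result is sorted with strictly increasing times.  Idempotent.
    """
    merged: dict[int, float] = {}
    for ev in _as_events(events):
        merged[ev.time_min] = merged.get(ev.time_min, 0.0) + ev.energy_kcal
    return [EatingEvent(t, merged[t]) for t in sorted(merged)]


def events_to_minute_series(events: Iterable) -> np.ndarray:
    """Expand eating events into a length-1440 kcal/min series.

    Each event spreads its energy uniformly over the half-open 15-minute
    window [t, t+15); overlapping windows add.  Windows running past
    minute 1439 are truncated at the end of the day (no wraparound), so
    the series sum can fall short of the total event energy only for
    events starting after minute 1425.
    """
    evs = _as_events(events)
    if not evs:
        raise ValueError("empty event list: recalls must have non-zero energy intake")
    series = np.zeros(MINUTES_PER_DAY)
    for ev in evs:
        stop = min(ev.time_min + OCCASION_MINUTES, MINUTES_PER_DAY)
        series[ev.time_min : stop] += ev.energy_kcal / OCCASION_MINUTES
    return series


@dataclass
class RecallDay:
    """One participant's 24-h recall as a time-ordered event sequence."""

    participant_id: str
    events: list[EatingEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = _as_events(self.events)
        if not self.events:
            raise ValueError(f"recall {self.participant_id}: no events")
        self.events.sort(key=lambda ev: ev.time_min)
        if self.total_energy <= 0:
            raise ValueError(f"recall {self.participant_id}: non-positive total energy")

    @property
    def total_energy(self) -> float:
        return sum(ev.energy_kcal for ev in self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([ev.time_min for ev in self.events], dtype=float)

    @property
    def energies(self) -> np.ndarray:
        return np.array([ev.energy_kcal for ev in self.events], dtype=float)

    def merged(self) -> "RecallDay":
        return RecallDay(self.participant_id, merge_simultaneous_events(self.events))

    def minute_series(self) -> np.ndarray:
        return events_to_minute_series(self.events)


def parse_clock_time(value) -> int:
    """Minute-of-day from an integer or an ``HH:MM`` string (00:00 = 0)."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.split(":")
        minute = int(hh) * 60 + int(mm)
    else:
        minute = int(value)
    if not 0 <= minute < MINUTES_PER_DAY:
        raise ValueError(f"clock time {value!r} outside the day")
    return minute


def read_events_csv(path) -> pd.DataFrame:
    """Read an event table (participant_id, time_min, energy_kcal).

    ``time_min`` may hold integers or HH:MM clock strings.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["time_min"] = df["time_min"].map(parse_clock_time)
    df["energy_kcal"] = df["energy_kcal"].astype(float)
    return df


def recalls_from_events(events: pd.DataFrame, merge: bool = True) -> list[RecallDay]:
    """Group an event table into per-participant :class:`RecallDay` objects."""
    recalls = []
    for pid, grp in events.groupby("participant_id", sort=True):
        evs = list(zip(grp["time_min"], grp["energy_kcal"]))
        if merge:
            evs = merge_simultaneous_events(evs)
        recalls.append(RecallDay(str(pid), evs))
    return recalls


def events_frame(recalls: Sequence[RecallDay]) -> pd.DataFrame:
    """Flatten recalls back to the long event-table layout."""
    rows = [
        (r.participant_id, ev.time_min, ev.energy_kcal)
        for r in recalls
        for ev in r.events
    ]
    return pd.DataFrame(rows, columns=["participant_id", "time_min", "energy_kcal"])
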