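"""Experiment and hypnogram containers.

An :class:`Experiment` bundles all event trains of a recording campaign
(every mouse, neuron and session), the session durations, and the
vigilance-state hypnogram of the consolidation recording.  The neuron
order is fixed at construction (sorted by mouse id, then neuron id) and
shared by every activity vector built from the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import SESSIONS, BinnedActivity, EventTrain, bin_events

#: Vigilance states of the hypnogram.
STATES = ("wake", "NREM", "REM")

#: Protocol session durations in seconds (preC 10 min, preS 10 min,
#: postS 5 min, consolidation recording 150 min, test 10 min).
DEFAULT_SESSION_DURATIONS = {
    "preC": 600.0,
    "preS": 600.0,
    "postS": 300.0,
    "consolidation": 9000.0,
    "test": 600.0,
}


@dataclass(frozen=True)
class Hypnogram:
    """Non-overlapping, sorted vigilance-state intervals ``(start_s, end_s, state)``."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        iv = tuple((float(s), float(e), str(st)) for s, e, st in self.intervals)
        prev_end = None
        for s, e, st in iv:
            if st not in STATES:
                raise ValueError(f"unknown state {st!r}")
            if not e > s:
                raise ValueError(f"interval ({s}, {e}) must have positive length")
            if prev_end is not None and s < prev_end:
                raise ValueError("hypnogram intervals overlap or are unsorted")
            prev_end = e
        object.__setattr__(self, "intervals", iv)

    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def end(self) -> float:
        return self.intervals[-1][1]

    def covers(self, t0: float, t1: float, *, tol: float = 1e-9) -> bool:
        """True when the intervals cover ``[t0, t1]`` without gaps."""
        if not self.intervals or self.start > t0 + tol or self.end < t1 - tol:
            return False
        for (s0, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if s1 > e0 + tol:
                return False
        return True

    def restrict(
        self, states, t0: float | None = None, t1: float | None = None
    ) -> list[tuple[float, float]]:
        """Intersections of the given states' intervals with ``[t0, t1)``."""
        states = {states} if isinstance(states, str) else set(states)
        out: list[tuple[float, float]] = []
        for s, e, st in self.intervals:
            if st not in states:
                continue
            lo = s if t0 is None else max(s, t0)
            hi = e if t1 is None else min(e, t1)
            if hi > lo:
                out.append((lo, hi))
        return out

    def state_seconds(
        self, states, t0: float | None = None, t1: float | None = None
    ) -> float:
        return float(sum(e - s for s, e in self.restrict(states, t0, t1)))


def to_state_time(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Map event times into the cumulative time coordinate of an interval union.

    Events outside the intervals are dropped.  Used to build contiguous
    binned traces of state-restricted activity.
    """
    out = []
    offset = 0.0
    for s, e in intervals:
        inside = times[(times >= s) & (times < e)]
        out.append(inside - s + offset)
        offset += e - s
    return np.concatenate(out) if out else np.empty(0)


@dataclass
class Experiment:
    """All event trains of one experiment, plus session metadata.

    ``trains`` maps ``(mouse_id, neuron_id, session)`` to an
    :class:`~abnremap.events.EventTrain`; a neuron silent in a session
    may simply be absent (treated as an empty train by most analyses).
    """

    trains: dict[tuple[str, str, str], EventTrain]
    session_durations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SESSION_DURATIONS)
    )
    hypnogram: Hypnogram | None = None
    #: Fixed (mouse_id, neuron_id) order shared by all activity vectors.
    neuron_index: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (mouse, neuron, session), train in self.trains.items():
            if session not in SESSIONS:
                raise ValueError(f"unknown session {session!r}")
            if (train.mouse_id, train.neuron_id, train.session) != (mouse, neuron, session):
                raise ValueError("train key does not match train metadata")
            dur = self.session_durations.get(session)
            if dur is None:
                raise ValueError(f"no duration for session {session!r}")
            if train.n_events and train.times[-1] > dur:
                raise ValueError(
                    f"{mouse}/{neuron}/{session}: event beyond session duration"
                )
        if not self.neuron_index:
            self.neuron_index = sorted({(m, n) for m, n, _ in self.trains})

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_index)

    @property
    def mice(self) -> list[str]:
        seen: dict[str, None] = {}
        for m, _ in self.neuron_index:
            seen.setdefault(m)
        return list(seen)

    def get(self, mouse: str, neuron: str, session: str) -> EventTrain | None:
        return self.trains.get((mouse, neuron, session))

    def train_or_empty(self, mouse: str, neuron: str, session: str) -> EventTrain:
        train = self.get(mouse, neuron, session)
        if train is None:
            train = EventTrain(
                neuron_id=neuron,
                mouse_id=mouse,
                session=session,
                times=np.empty(0),
                amplitudes=np.empty(0),
            )
        return train

    def population_binned(self, session: str, bin_width: float) -> BinnedActivity:
        """Summed binned activity of every neuron in one session."""
        duration = self.session_durations[session]
        total = None
        for mouse, neuron in self.neuron_index:
            binned = bin_events(
                self.train_or_empty(mouse, neuron, session), bin_width, duration
            )
            total = binned.values if total is None else total + binned.values
        if total is None:
            raise ValueError("experiment has no neurons")
        return BinnedActivity(bin_width=float(bin_width), values=total)
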