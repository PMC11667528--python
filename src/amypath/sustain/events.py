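"""Z-score events and constrained event sequences.

An event is one marker crossing one of its z thresholds. A subtype is an
ordering (permutation) of all events in which each marker's thresholds
appear in increasing order — a marker cannot reach 2 SD before 1 SD.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterator, List, Sequence, Tuple

import numpy as np

from ..markers import MarkerPanel

__all__ = ["Event", "EventSequence", "all_events", "random_sequence",
           "enumerate_sequences", "valid_insert_positions"]


@dataclass(frozen=True, order=True)
class Event:
    """Marker ``marker_index`` crossing its ``threshold_index``-th z threshold."""

    marker_index: int
    threshold_index: int


def all_events(panel: MarkerPanel) -> List[Event]:
    return [Event(i, r) for i, m in enumerate(panel) for r in range(m.n_events)]


class EventSequence:
    """An ordering of the full event set, thresholds in-order per marker.

    Immutable; hashable; ``positions(marker)`` gives the 1-based stage
    positions of a marker's threshold events, the control points of its
    piecewise-linear trajectory.
    """

    __slots__ = ("events", "_pos")

    def __init__(self, events: Sequence[Event], panel: MarkerPanel):
        events = tuple(events)
        expected = all_events(panel)
        if sorted(events) != sorted(expected):
            raise ValueError("sequence must be a permutation of the full event set")
        seen = {}
        for k, ev in enumerate(events):
            prev = seen.get(ev.marker_index, -1)
            if ev.threshold_index != prev + 1:
                raise ValueError(
                    f"marker {ev.marker_index}: thresholds out of order at position {k}"
                )
            seen[ev.marker_index] = ev.threshold_index
        object.__setattr__(self, "events", events)
        pos = {}
        for k, ev in enumerate(events, start=1):
            pos.setdefault(ev.marker_index, []).append(k)
        object.__setattr__(self, "_pos", {m: tuple(p) for m, p in pos.items()})

    def __setattr__(self, *a):  # immutability
        raise AttributeError("EventSequence is immutable")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventSequence) and self.events == other.events

    def __hash__(self) -> int:
        return hash(self.events)

    def __repr__(self) -> str:
        body = ", ".join(f"({e.marker_index},{e.threshold_index})" for e in self.events)
        return f"EventSequence[{body}]"

    def positions(self, marker_index: int) -> Tuple[int, ...]:
        """1-based positions of the marker's threshold events, increasing."""
        return self._pos[marker_index]

    def position_of(self, event: Event) -> int:
        return self._pos[event.marker_index][event.threshold_index]

    def as_indices(self, panel: MarkerPanel) -> np.ndarray:
        """Event order encoded as indices into ``all_events(panel)``."""
        lookup = {ev: k for k, ev in enumerate(all_events(panel))}
        return np.array([lookup[ev] for ev in self.events], dtype=int)


def valid_insert_positions(rest: Sequence[Event], event: Event) -> range:
    """0-based insertion slots for ``event`` into ``rest`` that keep the
    marker's thresholds in order.

    ``rest`` is a sequence with the event removed. The slot range is bounded
    below by the previous threshold of the same marker and above by the next.
    """
    lo, hi = 0, len(rest)
    for k, ev in enumerate(rest):
        if ev.marker_index == event.marker_index:
            if ev.threshold_index < event.threshold_index:
                lo = k + 1
            elif ev.threshold_index > event.threshold_index:
                hi = min(hi, k)
                break
    return range(lo, hi + 1)


def random_sequence(panel: MarkerPanel, rng: np.random.Generator) -> EventSequence:
    """Uniformly random valid sequence (random keys, stable per-marker order)."""
    events = all_events(panel)
    keys = rng.random(len(events))
    # sort per marker so thresholds keep increasing keys, then globally
    by_marker = {}
    for ev, k in zip(events, keys):
        by_marker.setdefault(ev.marker_index, []).append(k)
    fixed = []
    for ev in events:
        ks = sorted(by_marker[ev.marker_index])
        fixed.append(ks[ev.threshold_index])
    order = np.argsort(np.array(fixed), kind="stable")
    return EventSequence([events[i] for i in order], panel)


def enumerate_sequences(panel: MarkerPanel) -> List[EventSequence]:
    """Every valid sequence; exponential, intended for tiny event spaces."""
    events = all_events(panel)
    if len(events) > 8:
        raise ValueError("event space too large to enumerate")
    out = []
    for perm in permutations(events):
        try:
            out.append(EventSequence(perm, panel))
        except ValueError:
            continue
    return out
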