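"""Event-calendar discrete-event simulation core.

A minimal, clinic-agnostic engine: entities follow a fixed route of stations;
each station is a capacity-constrained FIFO queue that may only start service
inside its opening windows (unless flagged work-to-finish, in which case it
keeps starting queued services after closing until the queue drains).  Events
are processed in non-decreasing time order with insertion-order tie-breaking,
so a run is fully deterministic given its inputs.

Time is continuous minutes; multi-day runs lay days end to end
(day ``d``, clock ``t`` -> ``1440*d + t``).
"""

from __future__ import annotations

import heapq
import itertools
import math
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["RouteStep", "Entity", "Station", "EventLog", "Engine"]

INF = math.inf


@dataclass(frozen=True)
class RouteStep:
    """One leg of an entity's itinerary.

    ``duration`` is the (pre-drawn) service time in minutes; ``transfer_after``
    is the walking time to the next station once service ends.
    """

    station: str
    duration: float
    transfer_after: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"negative service time at {self.station}: {self.duration}")
        if self.transfer_after < 0:
            raise ValueError("negative transfer time")


@dataclass
class Entity:
    """A simulated customer: identifier, class label, and a fixed route."""

    eid: int
    klass: str
    route: list[RouteStep]
    step_idx: int = 0

    @property
    def current_step(self) -> RouteStep:
        return self.route[self.step_idx]


class EventLog:
    """Complete record of one run: event stream plus per-entity visit trails.

    A trail entry is ``[station, queue_join, start, end, server]`` in visit
    order (a station may legitimately appear twice, e.g. a combined
    registration/payment counter).
    """

    def __init__(self, record_events: bool = True):
        self.record_events = record_events
        self.events: list[tuple] = []  # (time, seq, kind, eid, station)
        self.trails: dict[int, list[list]] = {}
        self.arrivals: dict[int, float] = {}
        self.departures: dict[int, float] = {}

    # -- recording -----------------------------------------------------
    def log(self, time: float, seq: int, kind: str, eid, station) -> None:
        if self.record_events:
            self.events.append((time, seq, kind, eid, station))

    def open_visit(self, eid: int, station: str, t: float) -> list:
        visit = [station, t, None, None, None]
        self.trails.setdefault(eid, []).append(visit)
        return visit

    # -- views ---------------------------------------------------------
    def visits(self, eid: int, station: str | None = None) -> list[list]:
        trail = self.trails.get(eid, [])
        if station is None:
            return trail
        return [v for v in trail if v[0] == station]

    def to_events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time", "seq", "kind", "entity", "station"])

    def to_patient_frame(self) -> pd.DataFrame:
        """One row per entity: arrival, departure, and per-visit milestones."""
        rows = []
        for eid, trail in self.trails.items():
            row: dict = {
                "entity": eid,
                "arrival": self.arrivals.get(eid),
                "departure": self.departures.get(eid),
            }
            seen: dict[str, int] = {}
            for station, join, start, end, server in trail:
                k = seen.get(station, 0)
                seen[station] = k + 1
                tag = station if k == 0 else f"{station}#{k + 1}"
                row[f"{tag}_join"] = join
                row[f"{tag}_start"] = start
                row[f"{tag}_end"] = end
            rows.append(row)
        return pd.DataFrame(rows)


class Station:
    """Capacity-constrained FIFO service station with opening windows."""

    def __init__(
        self,
        sid: str,
        capacity: int,
        windows: tuple[tuple[float, float], ...] = ((0.0, INF),),
        work_to_finish: bool = False,
    ):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.sid = sid
        self.capacity = capacity
        self.windows = tuple(sorted(windows))
        self.work_to_finish = work_to_finish
        self.queue: deque = deque()
        self.busy = 0
        self._wakes: set[float] = set()

    # -- window logic ----------------------------------------------------
    def _admissible(self, t: float) -> tuple[bool, float | None]:
        """May a service start at time t?  If not, when next (None = never)."""
        if self.work_to_finish:
            first_open = self.windows[0][0]
            return (t >= first_open, first_open if t < first_open else None)
        for open_, close in self.windows:
            if t < open_:
                return False, open_
            if t < close:
                return True, None
        return False, None

    # -- queue machinery ---------------------------------------------------
    def seize(self, eng: "Engine", entity, t: float) -> None:
        """Entity requests service; starts immediately if possible, else queues FIFO."""
        visit = eng.log.open_visit(entity.eid, self.sid, t)
        eng.log.log(t, eng.next_seq(), "queue_join", entity.eid, self.sid)
        self.queue.append((entity, visit))
        self.try_start(eng, t)

    def try_start(self, eng: "Engine", t: float) -> None:
        while self.queue and self.busy < self.capacity:
            ok, nxt = self._admissible(t)
            if not ok:
                if nxt is not None and nxt not in self._wakes:
                    self._wakes.add(nxt)
                    eng.schedule(nxt, lambda tt=nxt: (self._wakes.discard(tt), self.try_start(eng, tt)))
                return
            entity, visit = self.queue.popleft()
            self._start(eng, entity, visit, t)

    def _start(self, eng: "Engine", entity, visit, t: float) -> None:
        self.busy += 1
        visit[2] = t
        eng.log.log(t, eng.next_seq(), "service_start", entity.eid, self.sid)
        dur = entity.current_step.duration
        eng.schedule(t + dur, lambda: self._end(eng, entity, visit, t + dur))

    def _end(self, eng: "Engine", entity, visit, t: float) -> None:
        self.busy -= 1
        visit[3] = t
        eng.log.log(t, eng.next_seq(), "service_end", entity.eid, self.sid)
        eng.advance(entity, t)
        self.try_start(eng, t)

    def adjust_capacity(self, eng: "Engine", delta: int, t: float) -> None:
        """Temporarily add/remove servers (e.g. room blocked by a downtime episode)."""
        self.capacity += delta
        if self.capacity < 0:
            raise RuntimeError(f"{self.sid}: capacity below zero")
        eng.log.log(t, eng.next_seq(), "capacity_change", None, self.sid)
        if delta > 0:
            self.try_start(eng, t)


class Engine:
    """The event calendar: a (time, sequence) min-heap of callbacks."""

    def __init__(self, stations: dict[str, Station], record_events: bool = True):
        self.stations = stations
        self.log = EventLog(record_events=record_events)
        self._heap: list[tuple[float, int, object]] = []
        self._seq = itertools.count()
        self.now = 0.0

    def next_seq(self) -> int:
        return next(self._seq)

    def schedule(self, time: float, fn) -> None:
        if time < self.now - 1e-9:
            raise RuntimeError("event scheduled in the past")
        heapq.heappush(self._heap, (time, self.next_seq(), fn))

    def submit(self, entity, time: float) -> None:
        """Register an entity's arrival into the system at ``time``."""
        first = entity.route[0].station
        if first not in self.stations:
            raise KeyError(f"entity {entity.eid} routed to unknown station {first!r}")
        self.log.arrivals[entity.eid] = time
        self.schedule(time, lambda: self._arrive(entity, time))

    def _arrive(self, entity, t: float) -> None:
        self.log.log(t, self.next_seq(), "arrival", entity.eid, entity.current_step.station)
        self.stations[entity.current_step.station].seize(self, entity, t)

    def advance(self, entity, t: float) -> None:
        """Route an entity onward after a service completion."""
        step = entity.current_step
        entity.step_idx += 1
        if entity.step_idx >= len(entity.route):
            self.log.departures[entity.eid] = t
            self.log.log(t, self.next_seq(), "departure", entity.eid, None)
            return
        nxt = entity.current_step.station
        if nxt not in self.stations:
            raise KeyError(f"entity {entity.eid} routed to unknown station {nxt!r}")
        at = t + step.transfer_after
        self.log.log(t, self.next_seq(), "transfer", entity.eid, nxt)
        self.schedule(at, lambda: self.stations[nxt].seize(self, entity, at))

    def run(self, horizon: float = INF, check_empty: bool = True) -> EventLog:
        """Process the calendar until empty (or ``horizon``); return the log.

        With ``check_empty`` (default), raises if entities remain in the system
        when the calendar drains — a conservation violation.
        """
        while self._heap:
            time, _seq, fn = heapq.heappop(self._heap)
            if time > horizon:
                break
            self.now = time
            fn()
        if check_empty and not self._heap:
            stuck = len(self.log.arrivals) - len(self.log.departures)
            if stuck:
                raise RuntimeError(f"{stuck} entities never departed (stuck in closed stations?)")
        return self.log
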