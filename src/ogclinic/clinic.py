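"""The O&G clinic network: stations, staff, dual-practice rules, downtime.

Station layout (capacities configurable): shared QMS and revenue counters at
the outpatient department; at the clinic an O&G registration counter, a
designated private-patient counter, two vital-sign stations, a laboratory,
up to ten consultation rooms, and two nurses' stations.

Consultations are the interesting part.  Public patients are seen by a pool
of doctors — and, until the pre-private lunch break, by specialists — with the
patient at the head of the FIFO queue assigned uniformly at random among the
idle eligible providers, subject to a free room and the session start time.
Private patients are seen only by the dual-practice specialists, only after
their one-hour lunch break that precedes the private session.  A public
consultation flagged for specialist discussion is extended by the discussion
duration: if the serving provider is a specialist the discussion happens
inline, otherwise an idle specialist is co-seized (the patient keeps holding
the room and doctor while waiting for one).

The base case additionally carries a *downtime process*: Poisson-many
episodes per day during active clinic hours, each seizing one doctor together
with a consultation room for a sampled duration — the signature of an
atypical/prolonged consultation or an inactive room whose doctor is away on
other duties.  It is switched off in every scenario ("typical consultation
times").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import hhmm_to_minutes
from .engine import Engine, Station
from .patients import MINUTES_PER_DAY, Patient, generate_replication
from .streams import Streams

__all__ = ["Provider", "ConsultStation", "build_clinic", "run_replication"]


@dataclass
class Provider:
    name: str
    kind: str  # "doctor" | "specialist"
    private_ok: bool = False  # dual-practice specialist serving private patients
    public_ok: bool = True
    busy: bool = False


class ConsultStation(Station):
    """Consultation rooms + provider pools with session/lunch eligibility windows.

    ``capacity`` counts rooms; providers are a separate constraint.  Clock
    rules repeat daily: public consultations start at ``consult_start``;
    dual-practice specialists take public patients only before their lunch
    (``private_session - lunch``), and private patients only from
    ``private_session`` onward, both work-to-finish.
    """

    def __init__(
        self,
        rooms: int,
        providers: list[Provider],
        consult_start: float,
        private_session: float,
        lunch_minutes: float,
        assign_rng: np.random.Generator,
    ):
        super().__init__("CONSULT", capacity=rooms, work_to_finish=True)
        self.providers = providers
        self.consult_start = consult_start
        self.private_session = private_session
        self.lunch_start = private_session - lunch_minutes
        self.assign_rng = assign_rng
        from collections import deque

        self.public_queue: deque = deque()
        self.private_queue: deque = deque()
        self.discussion_queue: deque = deque()
        self.pending_blocks: deque = deque()  # downtime episodes waiting for an idle doctor

    # -- eligibility ---------------------------------------------------
    def _idle_for_public(self, clock: float) -> list[Provider]:
        out = []
        for p in self.providers:
            if p.busy or not p.public_ok:
                continue
            if p.kind == "doctor":
                out.append(p)
            elif p.private_ok:
                if clock < self.lunch_start:  # leaves for lunch, then private session
                    out.append(p)
            else:
                out.append(p)  # public-only specialist, work-to-finish
        return out

    def _idle_for_private(self, clock: float) -> list[Provider]:
        if clock < self.private_session:
            return []
        return [p for p in self.providers if p.private_ok and not p.busy]

    def _idle_specialist_for_discussion(self, clock: float) -> Provider | None:
        for p in self.providers:
            if p.kind != "specialist" or p.busy:
                continue
            if p.private_ok and self.lunch_start <= clock < self.private_session:
                continue  # at lunch
            return p
        return None

    # -- queue machinery -------------------------------------------------
    def seize(self, eng: Engine, entity: Patient, t: float) -> None:
        visit = eng.log.open_visit(entity.eid, self.sid, t)
        eng.log.log(t, eng.next_seq(), "queue_join", entity.eid, self.sid)
        if entity.is_private:
            self.private_queue.append((entity, visit))
        else:
            self.public_queue.append((entity, visit))
        self.try_start(eng, t)

    def _wake(self, eng: Engine, t_abs: float) -> None:
        if t_abs not in self._wakes:
            self._wakes.add(t_abs)
            eng.schedule(t_abs, lambda: (self._wakes.discard(t_abs), self.try_start(eng, t_abs)))

    def try_start(self, eng: Engine, t: float) -> None:
        day0 = MINUTES_PER_DAY * math.floor(t / MINUTES_PER_DAY)
        clock = t - day0
        progress = True
        while progress:
            progress = False
            # specialists owed to pending case discussions first: they unblock
            # a held room and doctor
            if self.discussion_queue:
                spec = self._idle_specialist_for_discussion(clock)
                if spec is not None:
                    entity, visit, prov = self.discussion_queue.popleft()
                    spec.busy = True
                    end = t + entity.discussion_time
                    eng.log.log(t, eng.next_seq(), "discussion_start", entity.eid, self.sid)
                    eng.schedule(end, lambda e=entity, v=visit, pr=prov, sp=spec, tt=end:
                                 self._discussion_end(eng, e, v, pr, sp, tt))
                    progress = True
                    continue
                if self.lunch_start <= clock < self.private_session:
                    self._wake(eng, day0 + self.private_session)
            if self.public_queue and self.busy < self.capacity:
                if clock < self.consult_start:
                    self._wake(eng, day0 + self.consult_start)
                else:
                    cands = self._idle_for_public(clock)
                    if cands:
                        entity, visit = self.public_queue.popleft()
                        prov = cands[int(self.assign_rng.integers(len(cands)))]
                        self._start_consult(eng, entity, visit, prov, t)
                        progress = True
            if self.private_queue and self.busy < self.capacity:
                if clock < self.private_session:
                    self._wake(eng, day0 + self.private_session)
                else:
                    cands = self._idle_for_private(clock)
                    if cands:
                        entity, visit = self.private_queue.popleft()
                        prov = cands[int(self.assign_rng.integers(len(cands)))]
                        self._start_consult(eng, entity, visit, prov, t)
                        progress = True

    def _start_consult(self, eng: Engine, entity: Patient, visit, prov: Provider, t: float) -> None:
        prov.busy = True
        self.busy += 1  # room
        visit[2] = t
        visit[4] = prov.name
        eng.log.log(t, eng.next_seq(), "service_start", entity.eid, self.sid)
        dur = entity.current_step.duration
        needs_disc = bool(entity.attrs and entity.attrs.needs_specialist_discussion)
        inline = needs_disc and prov.kind == "specialist"
        if inline:
            dur += entity.discussion_time
        pending = needs_disc and not inline
        end = t + dur
        eng.schedule(end, lambda: self._consult_end(eng, entity, visit, prov, end, pending))

    def _consult_end(self, eng: Engine, entity, visit, prov, t, pending_discussion: bool) -> None:
        if pending_discussion:
            clock = t - MINUTES_PER_DAY * math.floor(t / MINUTES_PER_DAY)
            spec = self._idle_specialist_for_discussion(clock)
            if spec is None:
                # room and doctor stay held until a specialist frees up
                self.discussion_queue.append((entity, visit, prov))
                if self.lunch_start <= clock < self.private_session:
                    day0 = t - clock
                    self._wake(eng, day0 + self.private_session)
                return
            spec.busy = True
            end = t + entity.discussion_time
            eng.log.log(t, eng.next_seq(), "discussion_start", entity.eid, self.sid)
            eng.schedule(end, lambda: self._discussion_end(eng, entity, visit, prov, spec, end))
            return
        self._finish(eng, entity, visit, prov, t)

    def _discussion_end(self, eng: Engine, entity, visit, prov, spec, t) -> None:
        spec.busy = False
        self._finish(eng, entity, visit, prov, t)

    def _finish(self, eng: Engine, entity, visit, prov, t) -> None:
        prov.busy = False
        self.busy -= 1
        visit[3] = t
        eng.log.log(t, eng.next_seq(), "service_end", entity.eid, self.sid)
        dur = self._pop_pending_block(t)
        if dur is not None and prov.kind == "doctor":
            self._apply_block(eng, prov, dur, t)
        eng.advance(entity, t)
        self.try_start(eng, t)

    # -- downtime: atypical/prolonged sessions occupying a doctor + room -----
    def block_doctor(self, eng: Engine, t: float, duration: float,
                     expiry: float = math.inf) -> None:
        """A downtime episode seizes an idle doctor and a room for ``duration``.

        If every doctor is busy the episode waits for the next one to free up
        (the room is then guaranteed free as rooms >= providers here), but
        lapses if no doctor frees up before ``expiry`` — doctor unavailability
        is a clinic-hours phenomenon and must not pile into the evening.
        """
        for p in self.providers:
            if p.kind == "doctor" and not p.busy:
                self._apply_block(eng, p, duration, t)
                return
        self.pending_blocks.append((duration, expiry))

    def _pop_pending_block(self, t: float) -> float | None:
        while self.pending_blocks:
            duration, expiry = self.pending_blocks.popleft()
            if t < expiry:
                return duration
        return None

    def _apply_block(self, eng: Engine, prov: Provider, duration: float, t: float) -> None:
        prov.busy = True
        self.busy += 1
        eng.log.log(t, eng.next_seq(), "downtime_start", None, self.sid)

        def release(end=t + duration):
            prov.busy = False
            self.busy -= 1
            eng.log.log(end, eng.next_seq(), "downtime_end", None, self.sid)
            dur = self._pop_pending_block(end)
            if dur is not None:
                self._apply_block(eng, prov, dur, end)
            self.try_start(eng, end)

        eng.schedule(t + duration, release)


def _make_providers(res: dict) -> list[Provider]:
    n_doc = int(res["doctors"])
    n_spec = int(res["specialists"])
    n_priv = int(res["private_specialists"])
    if n_priv > n_spec:
        raise ValueError("private_specialists cannot exceed specialists")
    see_public = bool(res.get("specialists_see_public", True))
    providers = [Provider(f"doctor_{i}", "doctor") for i in range(n_doc)]
    for i in range(n_spec):
        providers.append(
            Provider(f"specialist_{i}", "specialist",
                     private_ok=(i < n_priv), public_ok=see_public)
        )
    return providers


def _schedule_downtime(eng: Engine, consult: ConsultStation, config: dict,
                       days: int, rng: np.random.Generator) -> None:
    dt = config["downtime"]
    rate = float(dt["episodes_per_day"])
    dmin, dmax = float(dt["duration_min"]), float(dt["duration_max"])
    w0, w1 = (hhmm_to_minutes(x) for x in dt["window"])
    for day in range(days):
        base = MINUTES_PER_DAY * day
        expiry = base + w1
        for _ in range(int(rng.poisson(rate))):
            start = base + rng.uniform(w0, w1)
            dur = rng.uniform(dmin, dmax)
            eng.schedule(start, lambda s=start, d=dur: consult.block_doctor(eng, s, d, expiry))


def build_clinic(config: dict, scenario, days: int, streams: Streams,
                 record_events: bool = True) -> Engine:
    """Assemble the engine for one replication of ``days`` clinic days."""
    res = config["resources"]
    open_ = hhmm_to_minutes(config["timing"]["counters_open"])
    close = hhmm_to_minutes(config["timing"]["counters_close"])
    counter_windows = tuple(
        (MINUTES_PER_DAY * d + open_, MINUTES_PER_DAY * d + close) for d in range(days)
    )

    private_session = max(
        scenario.private_open, hhmm_to_minutes(config["timing"]["earliest_private_session"])
    )
    rooms_override = getattr(scenario, "consult_rooms", None)
    consult = ConsultStation(
        rooms=int(rooms_override if rooms_override else res["consult_rooms"]),
        providers=_make_providers(res),
        consult_start=scenario.consult_start,
        private_session=private_session,
        lunch_minutes=float(config["timing"]["specialist_lunch_minutes"]),
        assign_rng=streams["assignment"],
    )
    stations = {
        # registration counters stop admitting at close; clinic stations are
        # work-to-finish (staff serve out the queue past closing)
        "QMS": Station("QMS", int(res["qms_servers"]), counter_windows),
        "REVENUE": Station("REVENUE", int(res["revenue_servers"]), counter_windows),
        "OG_COUNTER": Station("OG_COUNTER", int(res["og_counter_servers"]),
                              counter_windows, work_to_finish=True),
        "PRIVATE_COUNTER": Station("PRIVATE_COUNTER", int(res["private_counter_servers"]),
                                   counter_windows, work_to_finish=True),
        "VITALS": Station("VITALS", int(res["vitals_stations"]), counter_windows, work_to_finish=True),
        "LAB": Station("LAB", int(res["lab_servers"]), counter_windows, work_to_finish=True),
        "NURSES": Station("NURSES", int(res["nurses_stations"]), counter_windows, work_to_finish=True),
        "CONSULT": consult,
    }
    eng = Engine(stations, record_events=record_events)
    if scenario.downtime_enabled:
        _schedule_downtime(eng, consult, config, days, streams["downtime"])
    return eng


def run_replication(config: dict, scenario, days: int, master_seed: int,
                    replication: int = 0, record_events: bool = False):
    """Generate one replication's patients, simulate, and return (log, patients)."""
    streams = Streams(master_seed, replication)
    patients = generate_replication(config, scenario, days, streams)
    eng = build_clinic(config, scenario, days, streams, record_events=record_events)
    for p in patients:
        eng.submit(p, p.arrival_time)
    log = eng.run()
    return log, {p.eid: p for p in patients}
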