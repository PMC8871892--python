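"""Patient entities: classes, attributes, pre-drawn service times and routes.

Four patient classes flow through the model:

* ``GENERAL`` — patients of the other specialist clinics; they load the shared
  QMS and revenue counters and then leave the modelled system.
* ``PUBLIC_OBS`` / ``PUBLIC_GYN`` — public O&G patients: QMS -> revenue ->
  O&G counter -> vital signs -> (laboratory if needed) -> consultation
  (doctor, optionally extended by a specialist case discussion) -> nurses'
  station (next appointment) -> exit.
* ``PRIVATE`` — fee-for-service patients: designated private counter
  (registration) -> vital signs -> (laboratory) -> specialist-only
  consultation -> private counter again (payment/appointment) -> exit.

All service durations are drawn *at generation time* from per-station
substreams in a fixed patient order, so two scenarios run under the same
master seed give every patient identical attributes and service times
(common random numbers); only arrival instants differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arrivals import ArrivalSchedule, arrivals_for_day
from .config import hhmm_to_minutes, service_spec
from .engine import Entity, RouteStep
from .quantiles import QuantileSpec, ServiceDistribution, fit_quantile_distribution
from .streams import Streams

__all__ = [
    "PATIENT_CLASSES",
    "PatientAttributes",
    "Patient",
    "assign_attributes",
    "DistributionTable",
    "generate_replication",
]

PATIENT_CLASSES = ("GENERAL", "PUBLIC_OBS", "PUBLIC_GYN", "PRIVATE")

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class PatientAttributes:
    patient_class: str
    age_group: str  # "elderly" | "non_elderly"
    appointment_type: str  # "follow_up" | "new" | "walk_in"
    needs_lab: bool
    needs_specialist_discussion: bool


@dataclass
class Patient(Entity):
    attrs: PatientAttributes | None = None
    discussion_time: float = 0.0
    day: int = 0
    arrival_time: float = 0.0  # absolute minutes (1440*day + clock)

    @property
    def is_private(self) -> bool:
        return self.klass == "PRIVATE"


def assign_attributes(patient_class: str, rng: np.random.Generator, config: dict) -> PatientAttributes:
    """Draw a patient's attributes from the configured class-conditional rates.

    Exactly four uniforms are consumed per call regardless of class, keeping
    the attribute substream aligned across configurations.  Specialist
    discussion is only possible for public patients — private patients are
    seen by specialists directly.
    """
    if patient_class not in PATIENT_CLASSES:
        raise ValueError(f"unknown patient class {patient_class!r}")
    a = config["attributes"]
    u = rng.random(4)
    public = patient_class in ("PUBLIC_OBS", "PUBLIC_GYN")
    needs_lab = u[0] < a["needs_lab"].get(patient_class, 0.0)
    discussion = public and (u[1] < a["p_specialist_discussion"])
    age = "elderly" if u[2] < a["p_elderly"] else "non_elderly"
    appt = "walk_in" if u[3] < a["p_walk_in"] else "follow_up"
    return PatientAttributes(patient_class, age, appt, needs_lab, discussion)


class DistributionTable:
    """Cache of fitted service distributions per (station, class)."""

    def __init__(self, config: dict):
        self._config = config
        self._cache: dict[tuple[str, str], ServiceDistribution] = {}

    def get(self, station: str, klass: str) -> ServiceDistribution:
        key = (station, klass)
        dist = self._cache.get(key)
        if dist is None:
            q1, med, q3 = service_spec(self._config, station, klass)
            dist = self._cache[key] = fit_quantile_distribution(QuantileSpec(q1, med, q3))
        return dist


def _public_schedule(scenario, config) -> ArrivalSchedule:
    pattern = "block_random" if scenario.arrival_pattern == "random" else "even_staggered"
    return ArrivalSchedule(
        pattern=pattern,
        registration_open=scenario.qms_open,
        last_slot_start=scenario.last_public_slot,
        per_slot_cap=scenario.public_slot_cap,
        daily_total=int(config["volumes"]["public_per_day"]),
        patient_class="PUBLIC",
        block_weights=tuple(config["arrival_shape"]["public"]),
    )


def _private_schedule(scenario, config) -> ArrivalSchedule:
    pattern = "block_random" if scenario.arrival_pattern == "random" else "even_staggered"
    weights = tuple(config["arrival_shape"]["private"])
    last = scenario.private_open + 30.0 * (len(weights) - 1) if pattern == "block_random" else None
    return ArrivalSchedule(
        pattern=pattern,
        registration_open=scenario.private_open,
        last_slot_start=last,
        per_slot_cap=scenario.private_slot_cap,
        daily_total=int(config["volumes"]["private_per_day"]),
        patient_class="PRIVATE",
        block_weights=weights,
    )


def _general_schedule(config) -> ArrivalSchedule:
    """General (non-O&G) patients always arrive in the uncontrolled block pattern."""
    shape = config["arrival_shape"]
    weights = tuple(shape["general"])
    open_ = hhmm_to_minutes(config["timing"]["counters_open"])
    return ArrivalSchedule(
        pattern="block_random",
        registration_open=open_,
        last_slot_start=open_ + 30.0 * (len(weights) - 1),
        per_slot_cap=int(shape["general_slot_cap"]),
        daily_total=int(config["volumes"]["general_per_day"]),
        patient_class="GENERAL",
        block_weights=weights,
    )


def _build_route(patient: Patient, draws: dict[str, float], transfer: float) -> list[RouteStep]:
    if patient.klass == "GENERAL":
        names = ["QMS", "REVENUE"]
    elif patient.is_private:
        names = ["PRIVATE_COUNTER", "VITALS"]
        if patient.attrs.needs_lab:
            names.append("LAB")
        names += ["CONSULT", "PRIVATE_COUNTER#2"]
    else:
        names = ["QMS", "REVENUE", "OG_COUNTER", "VITALS"]
        if patient.attrs.needs_lab:
            names.append("LAB")
        names += ["CONSULT", "NURSES"]
    steps = []
    for i, name in enumerate(names):
        station = name.split("#")[0]
        steps.append(
            RouteStep(
                station=station,
                duration=draws[name],
                transfer_after=transfer if i < len(names) - 1 else 0.0,
            )
        )
    return steps


def generate_replication(config: dict, scenario, days: int, streams: Streams) -> list[Patient]:
    """Generate every patient of a replication, attributes and services pre-drawn.

    Patients are created in a fixed order (per day: public, private, general;
    within a class, in arrival-time order), each consuming a fixed number of
    draws from each substream, which is what makes cross-scenario runs share
    random numbers patient-for-patient.
    """
    dists = DistributionTable(config)
    transfer = float(config["timing"]["transfer_minutes"])
    att_rng = streams["attributes"]
    svc = {name: streams[f"service_{name.lower()}"] for name in
           ("QMS", "REVENUE", "OG_COUNTER", "PRIVATE_COUNTER", "VITALS", "LAB",
            "CONSULT", "NURSES", "DISCUSSION")}

    pub_sched = _public_schedule(scenario, config)
    prv_sched = _private_schedule(scenario, config)
    gen_sched = _general_schedule(config)
    p_obs = float(config["attributes"]["p_obs"])

    patients: list[Patient] = []
    eid = 0
    for day in range(days):
        pub_times = arrivals_for_day(pub_sched, streams["arrivals_public"])
        prv_times = arrivals_for_day(prv_sched, streams["arrivals_private"])
        gen_times = arrivals_for_day(gen_sched, streams["arrivals_general"])

        for t in pub_times:
            klass = "PUBLIC_OBS" if att_rng.random() < p_obs else "PUBLIC_GYN"
            attrs = assign_attributes(klass, att_rng, config)
            draws = {
                "QMS": dists.get("QMS", klass).sample(svc["QMS"]),
                "REVENUE": dists.get("REVENUE", klass).sample(svc["REVENUE"]),
                "OG_COUNTER": dists.get("OG_COUNTER", klass).sample(svc["OG_COUNTER"]),
                "VITALS": dists.get("VITALS", klass).sample(svc["VITALS"]),
                "LAB": dists.get("LAB", "PUBLIC_OBS").sample(svc["LAB"]),
                "CONSULT": dists.get("CONSULT", klass).sample(svc["CONSULT"]),
                "NURSES": dists.get("NURSES", klass).sample(svc["NURSES"]),
            }
            disc = dists.get("DISCUSSION", klass).sample(svc["DISCUSSION"])
            p = Patient(eid=eid, klass=klass, route=[], attrs=attrs,
                        discussion_time=float(disc), day=day,
                        arrival_time=MINUTES_PER_DAY * day + float(t))
            p.route = _build_route(p, draws, transfer)
            patients.append(p)
            eid += 1

        for t in prv_times:
            attrs = assign_attributes("PRIVATE", att_rng, config)
            draws = {
                "PRIVATE_COUNTER": dists.get("PRIVATE_COUNTER", "PRIVATE").sample(svc["PRIVATE_COUNTER"]),
                "PRIVATE_COUNTER#2": dists.get("PRIVATE_COUNTER", "PRIVATE").sample(svc["PRIVATE_COUNTER"]),
                "VITALS": dists.get("VITALS", "PRIVATE").sample(svc["VITALS"]),
                "LAB": dists.get("LAB", "PRIVATE").sample(svc["LAB"]),
                "CONSULT": dists.get("CONSULT", "PRIVATE").sample(svc["CONSULT"]),
            }
            p = Patient(eid=eid, klass="PRIVATE", route=[], attrs=attrs,
                        day=day, arrival_time=MINUTES_PER_DAY * day + float(t))
            p.route = _build_route(p, draws, transfer)
            patients.append(p)
            eid += 1

        for t in gen_times:
            attrs = assign_attributes("GENERAL", att_rng, config)
            draws = {
                "QMS": dists.get("QMS", "GENERAL").sample(svc["QMS"]),
                "REVENUE": dists.get("REVENUE", "GENERAL").sample(svc["REVENUE"]),
            }
            p = Patient(eid=eid, klass="GENERAL", route=[], attrs=attrs,
                        day=day, arrival_time=MINUTES_PER_DAY * day + float(t))
            p.route = _build_route(p, draws, transfer)
            patients.append(p)
            eid += 1

    return patients
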