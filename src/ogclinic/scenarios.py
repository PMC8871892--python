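"""The study design: base case and the seven scheduling/arrival scenarios.

Each scenario changes only *when* patients arrive and when consultations
start — never resource counts or daily patient totals.  The base case uses the
observed block ("random") arrival pattern and carries the calibrated downtime
process; every scenario uses typical consultation times (downtime off) and an
even/staggered arrival pattern.

Clock values are clock-minutes from midnight.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .clinic import run_replication
from .config import hhmm_to_minutes

__all__ = ["ScenarioConfig", "SCENARIO_IDS", "make_scenario", "ReplicationSet", "run_experiment"]


@dataclass(frozen=True)
class ScenarioConfig:
    id: str
    arrival_pattern: str  # "random" | "even"
    qms_open: float  # first public arrival slot (clock-minutes)
    consult_start: float
    public_slot_cap: int
    last_public_slot: float
    private_open: float
    private_slot_cap: int
    downtime_enabled: bool
    #: rooms override; None = configured default.  One scenario trades the
    #: 10-room maximum for 7 effective rooms to reflect doctors' other duties.
    consult_rooms: int | None = None

    def __post_init__(self) -> None:
        if self.arrival_pattern not in ("random", "even"):
            raise ValueError(f"unknown arrival pattern {self.arrival_pattern!r}")
        if self.downtime_enabled and self.id != "base":
            raise ValueError("downtime is a base-case-only feature")
        if self.last_public_slot < self.qms_open:
            raise ValueError("last public slot precedes opening")


def _row(sid, pattern, qms, consult, cap, last, popen, pcap, downtime,
         rooms=None) -> ScenarioConfig:
    return ScenarioConfig(
        id=sid,
        arrival_pattern=pattern,
        qms_open=hhmm_to_minutes(qms),
        consult_start=hhmm_to_minutes(consult),
        public_slot_cap=cap,
        last_public_slot=hhmm_to_minutes(last),
        private_open=hhmm_to_minutes(popen),
        private_slot_cap=pcap,
        downtime_enabled=downtime,
        consult_rooms=rooms,
    )


# Base case reflects the observed operation (~9:00 consultations, block
# arrival capped at 22/slot, private registration from 11:30); the tilde
# times are modelled as exact.
_SCENARIOS = {
    "base": _row("base", "random", "07:00", "09:00", 22, "12:00", "11:30", 9, True),
    "1": _row("1", "even", "07:00", "09:00", 22, "12:00", "11:30", 9, False),
    "2": _row("2", "even", "07:00", "08:15", 22, "12:00", "11:30", 9, False),
    "3": _row("3", "even", "07:30", "08:15", 10, "12:00", "13:30", 2, False),
    "4": _row("4", "even", "07:30", "09:00", 10, "12:00", "13:30", 2, False),
    "5": _row("5", "even", "08:00", "09:00", 7, "15:00", "11:30", 9, False, rooms=7),
    "6": _row("6", "even", "08:00", "09:00", 10, "12:30", "13:30", 2, False),
    "7": _row("7", "even", "08:00", "09:00", 10, "12:30", "11:00", 2, False),
}

SCENARIO_IDS = tuple(_SCENARIOS)


def make_scenario(scenario_id) -> ScenarioConfig:
    """Return the configuration row for ``base`` or scenarios ``1``–``7``."""
    key = str(scenario_id)
    try:
        return _SCENARIOS[key]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}") from None


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a custom scenario from a mapping with HH:MM clock fields."""
    return _row(
        str(d.get("id", "custom")),
        d["arrival_pattern"],
        d["qms_open"],
        d["consult_start"],
        int(d["public_slot_cap"]),
        d["last_public_slot"],
        d["private_open"],
        int(d["private_slot_cap"]),
        bool(d.get("downtime_enabled", False)),
    )


@dataclass
class ReplicationSet:
    """Seeded replications of one scenario, with their logs and patients."""

    scenario: ScenarioConfig
    n_replications: int
    days: int
    master_seed: int
    logs: list = field(default_factory=list)
    patients: list = field(default_factory=list)  # list of {eid: Patient}

    def summary(self) -> dict:
        from .metrics import replication_summary

        return replication_summary(self)


def run_experiment(config: dict, scenario: ScenarioConfig, n_replications: int = 30,
                   days: int = 5, master_seed: int = 0,
                   record_events: bool = False) -> ReplicationSet:
    """Run seeded replications of a scenario against the calibrated clinic.

    Refuses to run if the configuration does not carry calibrated front-end
    parameters: run ``calibrate`` first (the packaged default configuration is
    already calibrated).
    """
    if n_replications < 1 or days < 1:
        raise ValueError("n_replications and days must be >= 1")
    if not config.get("calibration", {}).get("calibrated", False):
        raise RuntimeError(
            "clinic model is not calibrated: run `calibrate` (ogclinic calibrate) "
            "or supply a configuration with calibration.calibrated: true"
        )
    rs = ReplicationSet(scenario, n_replications, days, master_seed)
    for rep in range(n_replications):
        log, pats = run_replication(config, scenario, days, master_seed,
                                    replication=rep, record_events=record_events)
        rs.logs.append(log)
        rs.patients.append(pats)
    return rs


def median_overall_tt(repset: ReplicationSet, klass_prefix: str) -> float:
    """Pooled median overall turnaround time for a class ('PUBLIC' or 'PRIVATE')."""
    from .metrics import turnaround_times

    values = []
    for log, pats in zip(repset.logs, repset.patients):
        df = turnaround_times(log, pats)
        sel = df[df["klass"].str.startswith(klass_prefix)]
        values.extend(sel["overall_tt"].tolist())
    return statistics.median(values)
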