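"""Patient arrival generation: block ("random") vs. even (staggered) patterns.

Outpatient arrivals are organised in 30-minute appointment slots between the
registration opening time and the last slot.  Two regimes are supported:

* ``block_random`` — the uncontrolled regime: each day's total is allocated to
  slots by a weighted multinomial draw whose default weights concentrate the
  load in the early-morning peak, subject to a per-slot cap.
* ``even_staggered`` — the scheduling intervention: the daily total is split
  as evenly as possible across the slots (earlier slots take the remainder),
  never exceeding the cap.

Within a slot, arrival instants are uniform jitter.  All times are
clock-minutes from midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrivalSchedule", "slot_counts_even", "slot_counts_block", "generate_arrivals"]

SLOT_WIDTH = 30.0

#: Default block-arrival slot weights for a 07:00-12:00 morning clinic
#: (11 slots).  ~60% of the day's load falls between 08:00 and 10:00, the
#: observed peak window; the tail decays through late morning.
DEFAULT_BLOCK_WEIGHTS = (0.04, 0.06, 0.15, 0.15, 0.15, 0.15, 0.09, 0.08, 0.06, 0.04, 0.03)


@dataclass(frozen=True)
class ArrivalSchedule:
    """One patient class's daily arrival plan."""

    pattern: str  # "block_random" | "even_staggered"
    registration_open: float  # clock-minutes (first slot start)
    last_slot_start: float | None  # clock-minutes; None => just enough slots for the total
    per_slot_cap: int
    daily_total: int
    patient_class: str
    block_weights: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.pattern not in ("block_random", "even_staggered"):
            raise ValueError(f"unknown arrival pattern {self.pattern!r}")
        if self.daily_total < 0 or self.per_slot_cap < 0:
            raise ValueError("daily_total and per_slot_cap must be non-negative")
        if self.last_slot_start is not None and self.last_slot_start < self.registration_open:
            raise ValueError("last_slot_start precedes registration_open")

    @property
    def n_slots(self) -> int:
        if self.last_slot_start is not None:
            return int((self.last_slot_start - self.registration_open) // SLOT_WIDTH) + 1
        if self.daily_total == 0:
            return 0
        if self.per_slot_cap == 0:
            raise ValueError("cannot place arrivals with per_slot_cap == 0")
        return -(-self.daily_total // self.per_slot_cap)  # ceil

    @property
    def slot_starts(self) -> np.ndarray:
        return self.registration_open + SLOT_WIDTH * np.arange(self.n_slots)

    def validate_feasible(self) -> None:
        if self.daily_total == 0:
            return
        if self.daily_total > self.per_slot_cap * self.n_slots:
            raise ValueError(
                f"daily_total {self.daily_total} infeasible: "
                f"{self.n_slots} slots x cap {self.per_slot_cap}"
            )


def slot_counts_even(schedule: ArrivalSchedule) -> np.ndarray:
    """Even/staggered split: base count per slot, earlier slots take the remainder."""
    schedule.validate_feasible()
    n = schedule.n_slots
    if n == 0:
        return np.zeros(0, dtype=int)
    base, rem = divmod(schedule.daily_total, n)
    counts = np.full(n, base, dtype=int)
    counts[:rem] += 1
    if counts.max(initial=0) > schedule.per_slot_cap:
        raise ValueError("even split exceeds per-slot cap")  # unreachable after feasibility
    return counts


def slot_counts_block(schedule: ArrivalSchedule, rng: np.random.Generator) -> np.ndarray:
    """Weighted multinomial slot allocation with cap overflow pushed to neighbours.

    Excess above the cap in any slot is moved forward slot by slot (then
    backward if the tail is full), which preserves the daily total exactly.
    """
    schedule.validate_feasible()
    n = schedule.n_slots
    if n == 0:
        return np.zeros(0, dtype=int)
    weights = schedule.block_weights
    if weights is None:
        weights = DEFAULT_BLOCK_WEIGHTS
    w = np.asarray(weights, dtype=float)
    if w.size != n:
        # re-grid the weight profile onto the schedule's slot count
        w = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, w.size), w)
    w = w / w.sum()
    counts = rng.multinomial(schedule.daily_total, w).astype(int)
    cap = schedule.per_slot_cap
    for i in range(n):  # forward pass
        if counts[i] > cap:
            if i + 1 < n:
                counts[i + 1] += counts[i] - cap
            else:
                counts[i - 1] += counts[i] - cap
            counts[i] = cap
    for i in range(n - 1, -1, -1):  # backward pass mops up tail overflow
        if counts[i] > cap:
            counts[i - 1] += counts[i] - cap
            counts[i] = cap
    return counts


def _jitter_slot(count: int, slot_start: float, rng: np.random.Generator) -> np.ndarray:
    return np.sort(slot_start + SLOT_WIDTH * rng.random(count))


def arrivals_for_day(schedule: ArrivalSchedule, rng: np.random.Generator) -> np.ndarray:
    """Clock-minute arrival instants for one day (sorted)."""
    if schedule.pattern == "even_staggered":
        counts = slot_counts_even(schedule)
    else:
        counts = slot_counts_block(schedule, rng)
    starts = schedule.slot_starts
    parts = [_jitter_slot(int(c), s, rng) for c, s in zip(counts, starts) if c]
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def generate_arrivals(schedule: ArrivalSchedule, n_days: int, seed: int) -> list[tuple[int, float, str]]:
    """Generate ``(day, clock_minutes, patient_class)`` tuples, sorted by (day, time).

    Identical ``seed`` yields identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[tuple[int, float, str]] = []
    for day in range(n_days):
        times = arrivals_for_day(schedule, rng)
        out.extend((day, float(t), schedule.patient_class) for t in times)
    return out
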