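"""Outcome measures: turnaround times, hourly crowd, scenario comparisons.

Turnaround-time (TT) decomposition per O&G patient:

* ``registration_tt`` — first arrival (QMS for public, private counter for
  private patients) to completion of clinic registration (O&G counter /
  private counter).
* ``clinic_tt`` — clinic registration completion to departure.
* ``overall_tt`` — first arrival to departure.

The *crowd* series counts, per clock minute, the patients who have completed
clinic registration, have not departed, and are not currently in service at
any station — i.e. the people sitting in the waiting area — then averages
within left-closed clock hours and across days/replications.

Medians are pooled across all patients of all replications (per-replication
medians are also reported).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "turnaround_times",
    "hourly_crowd",
    "percent_change",
    "rank_tests",
    "replication_summary",
    "pooled_tt",
]

CROWD_HOURS = tuple(range(7, 17))  # left-closed clock hours 07:00 .. 16:00
MINUTES_PER_DAY = 1440


def _registration_end(log, eid: int, is_private: bool) -> float:
    station = "PRIVATE_COUNTER" if is_private else "OG_COUNTER"
    visits = log.visits(eid, station)
    if not visits or visits[0][3] is None:
        raise ValueError(f"patient {eid} has no completed registration at {station}")
    return visits[0][3]


def turnaround_times(log, patients: dict) -> pd.DataFrame:
    """Per-patient TT records for the O&G patients of one replication log.

    Raises if any O&G patient never departed (a conservation violation).
    """
    rows = []
    for eid, p in patients.items():
        if p.klass == "GENERAL":
            continue
        dep = log.departures.get(eid)
        if dep is None:
            raise ValueError(f"patient {eid} has no departure; log incomplete")
        arr = log.arrivals[eid]
        reg_end = _registration_end(log, eid, p.is_private)
        rows.append(
            {
                "entity": eid,
                "klass": p.klass,
                "day": p.day,
                "registration_tt": reg_end - arr,
                "clinic_tt": dep - reg_end,
                "overall_tt": dep - arr,
            }
        )
    return pd.DataFrame(rows)


def _waiting_intervals(log, eid: int, reg_end: float, departure: float) -> list[tuple[float, float]]:
    """Presence interval [reg_end, departure) minus in-service intervals."""
    busy = []
    for station, _join, start, end, _srv in log.visits(eid):
        if start is None or end is None:
            continue
        if end <= reg_end:
            continue
        busy.append((max(start, reg_end), end))
    busy.sort()
    out = []
    cur = reg_end
    for s, e in busy:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if departure > cur:
        out.append((cur, departure))
    return out


def hourly_crowd(log, patients: dict, days: int) -> pd.Series:
    """Mean waiting-area occupancy per clock hour, averaged over days.

    The per-minute membership count at integer minute ``m`` includes a patient
    iff registered-by ``m``, not yet departed, and not in service; the hourly
    value is the mean of its 60 per-minute counts.
    """
    n_min = MINUTES_PER_DAY * days + 1
    diff = np.zeros(n_min + 1)
    for eid, p in patients.items():
        if p.klass == "GENERAL":
            continue
        dep = log.departures.get(eid)
        if dep is None:
            continue
        reg_end = _registration_end(log, eid, p.is_private)
        for a, b in _waiting_intervals(log, eid, reg_end, dep):
            lo, hi = math.ceil(a), math.ceil(b)
            if hi > lo:
                diff[lo] += 1
                diff[min(hi, n_min)] -= 1
    per_minute = np.cumsum(diff[:-1])
    values = []
    for hour in CROWD_HOURS:
        chunks = [
            per_minute[MINUTES_PER_DAY * d + 60 * hour: MINUTES_PER_DAY * d + 60 * (hour + 1)]
            for d in range(days)
        ]
        values.append(float(np.mean(np.concatenate(chunks))))
    return pd.Series(values, index=list(CROWD_HOURS), name="crowd")


def percent_change(scenario_stat: float, base_stat: float) -> float:
    """100 x (scenario - base) / base; negative means a reduction."""
    if base_stat <= 0:
        raise ValueError(f"base statistic must be positive, got {base_stat}")
    return 100.0 * (scenario_stat - base_stat) / base_stat


# ---------------------------------------------------------------------------
# rank-based group comparisons
# ---------------------------------------------------------------------------

def _exact_mannwhitney_p(x, y) -> float:
    """One-sided exact p = P(U <= U_obs) by full enumeration of rank splits."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = len(x), len(y)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        count += u <= u_obs + 1e-9
        total += 1
    return count / total


def rank_tests(groups) -> dict:
    """Compare >=2 non-empty samples with the appropriate rank test.

    Two groups: Mann-Whitney U (two-sided, tie-corrected asymptotic p);
    three or more: Kruskal-Wallis H.  For combined n <= 12 with two groups an
    exact one-sided permutation p (full enumeration) is also reported as a
    cross-check.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    out: dict = {"n": [len(g) for g in groups]}
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="asymptotic")
        out.update(test="mannwhitney", statistic=float(res.statistic), pvalue=float(res.pvalue))
        if sum(len(g) for g in groups) <= 12:
            out["exact_one_sided_pvalue"] = _exact_mannwhitney_p(groups[0], groups[1])
    else:
        res = stats.kruskal(*groups)
        out.update(test="kruskal", statistic=float(res.statistic), pvalue=float(res.pvalue))
    return out


# ---------------------------------------------------------------------------
# replication-set summaries
# ---------------------------------------------------------------------------

_MEASURES = ("registration_tt", "clinic_tt", "overall_tt")


def pooled_tt(repset) -> pd.DataFrame:
    """All patients' TT records across replications, with a replication column."""
    frames = []
    for rep, (log, pats) in enumerate(zip(repset.logs, repset.patients)):
        df = turnaround_times(log, pats)
        df.insert(0, "replication", rep)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def replication_summary(repset) -> dict:
    """JSON-ready summary: pooled TT quartiles per class, per-rep medians, crowd."""
    tt = pooled_tt(repset)
    classes = sorted(tt["klass"].unique())
    summary: dict = {
        "scenario": repset.scenario.id,
        "n_replications": repset.n_replications,
        "days_per_replication": repset.days,
        "master_seed": repset.master_seed,
        "patients_per_replication": int(len(tt) / repset.n_replications),
        "turnaround_times": {},
        "per_replication_medians": {},
        "hourly_crowd": {},
    }
    for klass in classes:
        sub = tt[tt["klass"] == klass]
        summary["turnaround_times"][klass] = {
            m: {
                "median": float(sub[m].median()),
                "q1": float(sub[m].quantile(0.25)),
                "q3": float(sub[m].quantile(0.75)),
            }
            for m in _MEASURES
        }
        summary["per_replication_medians"][klass] = {
            m: [float(x) for x in sub.groupby("replication")[m].median()]
            for m in _MEASURES
        }
    crowd = np.mean(
        [hourly_crowd(log, pats, repset.days).to_numpy()
         for log, pats in zip(repset.logs, repset.patients)],
        axis=0,
    )
    summary["hourly_crowd"] = {f"{h:02d}:00": float(v) for h, v in zip(CROWD_HOURS, crowd)}
    return summary
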