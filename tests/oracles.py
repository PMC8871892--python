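"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written with a *different* algorithm from the
code under test: a state-scanning next-event simulator (no event calendar), a
grid-search distribution fit (no scipy optimiser), and a per-minute recount of
waiting patients (no interval arithmetic).
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_network(arrivals, routes, capacities):
    """Next-event simulation of a FIFO multi-server station network by state
    scanning.

    Parameters
    ----------
    arrivals : list of (entity_id, time)
    routes : dict entity_id -> list of (station, service_time, transfer_after)
    capacities : dict station -> server count

    Returns dict ``(entity_id, visit_idx) -> (station, join, start, end)`` and
    per-entity departure times.  Assumes distinct float event times (no ties).
    """
    pending = sorted(((t, eid, 0) for eid, t in arrivals))  # (time, entity, step)
    queues = {s: [] for s in capacities}  # list of (join_time, eid, step)
    in_service = {s: [] for s in capacities}  # list of (end_time, eid, step, start)
    records = {}
    departures = {}
    visit_no = {}

    def fill(station, now):
        q = queues[station]
        srv = in_service[station]
        while q and len(srv) < capacities[station]:
            join, eid, step = q.pop(0)
            svc = routes[eid][step][1]
            k = visit_no.get(eid, 0)
            visit_no[eid] = k + 1
            records[(eid, k)] = (station, join, now, now + svc)
            srv.append((now + svc, eid, step, now))

    while pending or any(in_service[s] for s in in_service):
        t_arr = pending[0][0] if pending else math.inf
        t_end, end_station = math.inf, None
        for s, srv in in_service.items():
            for end, *_ in srv:
                if end < t_end:
                    t_end, end_station = end, s
        if t_arr <= t_end:
            t, eid, step = pending.pop(0)
            station = routes[eid][step][0]
            queues[station].append((t, eid, step))
            fill(station, t)
        else:
            srv = in_service[end_station]
            idx = min(range(len(srv)), key=lambda i: srv[i][0])
            end, eid, step, _start = srv.pop(idx)
            transfer = routes[eid][step][2]
            if step + 1 < len(routes[eid]):
                pending.append((end + transfer, eid, step + 1))
                pending.sort()
            else:
                departures[eid] = end
            fill(end_station, end)
    return records, departures


def lindley_waits(arrival_times, service_times):
    """Single-server FIFO waits: W_i = max(0, D_{i-1} - A_i)."""
    waits, dep_prev = [], -math.inf
    for a, s in zip(arrival_times, service_times):
        w = max(0.0, dep_prev - a)
        waits.append(w)
        dep_prev = a + w + s
    return waits


def grid_fit_sigma(q1, median, q3, sigmas):
    """Brute-force grid search for the lognormal log-sd, median held exact."""
    z75 = 0.6744897501960817  # Phi^{-1}(0.75)
    best, best_sse = None, math.inf
    for sig in sigmas:
        lo = median * math.exp(-z75 * sig)
        hi = median * math.exp(z75 * sig)
        sse = (lo - q1) ** 2 + (hi - q3) ** 2
        if sse < best_sse:
            best, best_sse = sig, sse
    return best


def recount_crowd(log, patients, days, hours):
    """Per-minute membership recount of the waiting-area crowd (slow, direct).

    A patient counts at integer minute m iff registration completed by m,
    departure after m, and m is not inside any of their in-service intervals.
    """
    values = []
    for hour in hours:
        counts = []
        for day in range(days):
            for m in range(1440 * day + 60 * hour, 1440 * day + 60 * (hour + 1)):
                n = 0
                for eid, p in patients.items():
                    if p.klass == "GENERAL":
                        continue
                    dep = log.departures.get(eid)
                    if dep is None:
                        continue
                    station = "PRIVATE_COUNTER" if p.klass == "PRIVATE" else "OG_COUNTER"
                    reg_end = log.visits(eid, station)[0][3]
                    if not (reg_end <= m < dep):
                        continue
                    in_service = any(
                        s is not None and e is not None and s <= m < e
                        for _st, _j, s, e, _srv in log.visits(eid)
                    )
                    if not in_service:
                        n += 1
                counts.append(n)
        values.append(float(np.mean(counts)))
    return values


def exact_mannwhitney_enumeration(x, y):
    """All C(n+m, n) label assignments of the pooled ranks; one-sided P(U <= u)."""
    import itertools

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        us.append(ranks[list(comb)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    return float(np.mean(us <= u_obs + 1e-9))
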