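"""Turnaround times, hourly crowd, percent change, and rank tests."""

import numpy as np
import pytest
from scipy import stats

from ogclinic.engine import EventLog
from ogclinic.metrics import (
    hourly_crowd,
    percent_change,
    rank_tests,
    turnaround_times,
)
from ogclinic.patients import Patient, PatientAttributes

from .oracles import exact_mannwhitney_enumeration, recount_crowd


def _fake_patient(eid, klass):
    attrs = PatientAttributes(klass, "non_elderly", "follow_up", False, False)
    return Patient(eid=eid, klass=klass, route=[], attrs=attrs)


def _fake_log(entries, arrivals, departures):
    """Build an EventLog by hand: entries = {eid: [(station, join, start, end)]}."""
    log = EventLog(record_events=False)
    for eid, visits in entries.items():
        for station, join, start, end in visits:
            v = log.open_visit(eid, station, join)
            v[2], v[3] = start, end
    log.arrivals.update(arrivals)
    log.departures.update(departures)
    return log


def test_turnaround_decomposition_matches_subtraction():
    # arrival 07:00 (420), O&G registration done 07:45 (465), departure 09:24 (564)
    log = _fake_log(
        {0: [("QMS", 420, 421, 422), ("OG_COUNTER", 440, 460, 465),
             ("CONSULT", 500, 530, 545)]},
        arrivals={0: 420.0}, departures={0: 564.0},
    )
    df = turnaround_times(log, {0: _fake_patient(0, "PUBLIC_OBS")})
    row = df.iloc[0]
    assert row["registration_tt"] == 45.0
    assert row["clinic_tt"] == 99.0
    assert row["overall_tt"] == 144.0


def test_private_registration_uses_first_private_counter_visit():
    log = _fake_log(
        {1: [("PRIVATE_COUNTER", 690, 695, 700), ("CONSULT", 720, 750, 770),
             ("PRIVATE_COUNTER", 772, 772, 776)]},
        arrivals={1: 690.0}, departures={1: 776.0},
    )
    df = turnaround_times(log, {1: _fake_patient(1, "PRIVATE")})
    assert df.iloc[0]["registration_tt"] == 10.0
    assert df.iloc[0]["clinic_tt"] == 76.0


def test_missing_departure_raises():
    log = _fake_log({0: [("OG_COUNTER", 420, 421, 425)]}, {0: 420.0}, {})
    with pytest.raises(ValueError):
        turnaround_times(log, {0: _fake_patient(0, "PUBLIC_OBS")})


def test_tt_medians_match_independent_recomputation():
    """20 random hand-built logs: medians agree with a direct dict recompute."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(3, 12))
        entries, arrivals, departures, pats = {}, {}, {}, {}
        expected = []
        for eid in range(n):
            a = float(rng.uniform(420, 600))
            reg = a + float(rng.uniform(5, 60))
            dep = reg + float(rng.uniform(30, 180))
            entries[eid] = [("OG_COUNTER", a + 1, reg - 2, reg)]
            arrivals[eid], departures[eid] = a, dep
            pats[eid] = _fake_patient(eid, "PUBLIC_GYN")
            expected.append((reg - a, dep - reg, dep - a))
        df = turnaround_times(_fake_log(entries, arrivals, departures), pats)
        exp = np.median(np.asarray(expected), axis=0)
        got = df[["registration_tt", "clinic_tt", "overall_tt"]].median().to_numpy()
        assert np.allclose(got, exp)


class TestCrowd:
    def test_empty_log_all_zero(self):
        series = hourly_crowd(_fake_log({}, {}, {}), {}, days=1)
        assert (series == 0).all()

    def test_single_patient_half_hour_presence(self):
        # registered at 09:10, departs 09:40, never in service after registration
        log = _fake_log({0: [("OG_COUNTER", 540, 545, 550)]}, {0: 540.0}, {0: 580.0})
        series = hourly_crowd(log, {0: _fake_patient(0, "PUBLIC_OBS")}, days=1)
        assert series.loc[9] == pytest.approx(0.5)
        assert series.drop(9).sum() == 0

    def test_in_service_minutes_excluded(self):
        log = _fake_log(
            {0: [("OG_COUNTER", 540, 545, 550), ("CONSULT", 560, 570, 590)]},
            {0: 540.0}, {0: 600.0},
        )
        series = hourly_crowd(log, {0: _fake_patient(0, "PUBLIC_OBS")}, days=1)
        # present 550-600 (50 min) minus 20 min consult = 30 waiting minutes
        assert series.loc[9] == pytest.approx(30 / 60)

    def test_matches_brute_force_recount(self, config, battery_small):
        rs = battery_small["base"]
        log, pats = rs.logs[0], rs.patients[0]
        series = hourly_crowd(log, pats, rs.days)
        brute = recount_crowd(log, pats, rs.days, list(series.index))
        assert np.allclose(series.to_numpy(), brute)

    def test_inflating_waits_never_lowers_crowd_or_tt(self):
        """Scale every wait by 1.5 (services fixed): overall TT strictly rises
        and no hourly crowd value falls."""
        rng = np.random.default_rng(8)
        entries, arrivals, departures, pats = {}, {}, {}, {}
        entries2, departures2 = {}, {}
        for eid in range(20):
            a = float(rng.uniform(430, 700))
            wait1 = float(rng.uniform(10, 90))
            svc = float(rng.uniform(3, 15))
            reg = a + 2.0
            for lam, (e, d) in ((1.0, (entries, departures)), (1.5, (entries2, departures2))):
                start = reg + lam * wait1
                e[eid] = [("OG_COUNTER", a, a + 1, reg), ("CONSULT", reg, start, start + svc)]
                d[eid] = start + svc
            arrivals[eid] = a
            pats[eid] = _fake_patient(eid, "PUBLIC_OBS")
        base_log = _fake_log(entries, arrivals, departures)
        slow_log = _fake_log(entries2, arrivals, departures2)
        tt1 = turnaround_times(base_log, pats)["overall_tt"]
        tt2 = turnaround_times(slow_log, pats)["overall_tt"]
        assert (tt2 > tt1).all()
        c1 = hourly_crowd(base_log, pats, days=1)
        c2 = hourly_crowd(slow_log, pats, days=1)
        assert (c2.to_numpy() >= c1.to_numpy() - 1e-9).all()
        assert c2.sum() > c1.sum()


class TestPercentChange:
    @pytest.mark.parametrize("scenario,base,expected", [(60, 100, -40.0), (100, 100, 0.0),
                                                        (138, 120, 15.0)])
    def test_examples(self, scenario, base, expected):
        assert percent_change(scenario, base) == pytest.approx(expected)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            percent_change(50, 0)


class TestRankTests:
    def test_extreme_separation_exact_p_is_one_twentieth(self):
        out = rank_tests([[1, 2, 3], [4, 5, 6]])
        assert out["test"] == "mannwhitney"
        assert out["statistic"] == 0.0
        assert out["exact_one_sided_pvalue"] == pytest.approx(1 / 20)
        assert out["exact_one_sided_pvalue"] == pytest.approx(
            exact_mannwhitney_enumeration(np.array([1., 2, 3]), np.array([4., 5, 6]))
        )

    def test_identical_groups_h_zero_p_one(self):
        out = rank_tests([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert out["test"] == "kruskal"
        assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["pvalue"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([[1, 2], []])

    def test_kruskal_type_i_error_calibrated(self):
        """Under the null (3 groups, one distribution), rejection rate at
        alpha=0.05 stays within 3 SE of 0.05 over 1,000 simulations."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.lognormal(2.0, 0.5, 12) for _ in range(3)]
            if rank_tests(groups)["pvalue"] < 0.05:
                rejections += 1
        se = (0.05 * 0.95 / n_sim) ** 0.5
        assert abs(rejections / n_sim - 0.05) <= 3 * se

    def test_exact_and_asymptotic_p_agree_on_moderate_sample(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        out = rank_tests([x, y])
        exact_two_sided = min(1.0, 2 * min(out["exact_one_sided_pvalue"],
                                           1 - out["exact_one_sided_pvalue"]))
        assert out["pvalue"] == pytest.approx(exact_two_sided, abs=0.06)
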