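"""Unit and property tests for the patient-flow engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edsurge import (
    AcuityLevel,
    Path,
    Patient,
    ServiceTime,
    ServiceTimeConfig,
    StationSet,
    assign_acuity_and_path,
    export_event_log,
    read_event_log,
    sample_service_time,
    simulate_replication,
    waiting_time,
)
from edsurge.core import (
    PATH_STATIONS,
    ServiceKind,
    _assign_vector,
    _fifo_station,
)
from edsurge.scenarios import NORMAL_MIX, PATH_TABLE

from conftest import FixedArrivalScenario, capacities, fixed_service, make_scenario


# ---------------------------------------------------------------------------
# Service-time sampling


class TestServiceTime:
    @pytest.mark.parametrize(
        "kind, lo, hi, mean",
        [
            (ServiceKind.CONSULTATION, 15.0, 90.0, (15 + 45 + 90) / 3),
            (ServiceKind.OBSERVATION, 0.0, 60.0, (0 + 15 + 60) / 3),
            (ServiceKind.LAB, 30.0, 120.0, (30 + 75 + 120) / 3),
        ],
    )
    def test_triangular_support_and_mean(self, rng, kind, lo, hi, mean):
        cfg = ServiceTimeConfig.default()
        draws = cfg[kind].sample(rng, size=100_000)
        assert draws.min() >= lo and draws.max() <= hi
        # triangular sd < (hi-lo)/4, so 5 sigma of the mean estimate is ample
        assert draws.mean() == pytest.approx(mean, abs=5 * (hi - lo) / 4 / math.sqrt(1e5))

    def test_triage_gamma_mean_under_shape_scale_convention(self, rng):
        # Gamma(4.5, 0.7) read as shape/scale: mean 3.15 min
        cfg = ServiceTimeConfig.default()
        draws = cfg[ServiceKind.TRIAGE].sample(rng, size=100_000)
        sd = math.sqrt(4.5) * 0.7
        assert draws.mean() == pytest.approx(4.5 * 0.7, abs=5 * sd / math.sqrt(1e5))
        assert draws.min() >= 0

    def test_scalar_draw_in_support(self, rng):
        x = sample_service_time(ServiceKind.CONSULTATION, ServiceTimeConfig.default(), rng)
        assert 15.0 <= x <= 90.0

    def test_unknown_kind_is_configuration_error(self, rng):
        with pytest.raises(ValueError, match="no service-time distribution"):
            sample_service_time(ServiceKind.LAB, {}, rng)

    @pytest.mark.parametrize(
        "family, params",
        [
            ("gamma", (0.0, 1.0)),
            ("gamma", (4.5, -0.7)),
            ("triangular", (45, 15, 90)),  # min > mode
            ("triangular", (5, 5, 5)),  # degenerate support
            ("weibull", (1.0, 1.0)),
            ("fixed", (-1.0,)),
        ],
    )
    def test_invalid_distributions_rejected(self, family, params):
        with pytest.raises(ValueError):
            ServiceTime(family, params)


# ---------------------------------------------------------------------------
# Acuity / path assignment


class TestAssignment:
    def test_al3_only_mix_uses_paths_2_and_3(self, rng):
        counts = {p: 0 for p in Path}
        for _ in range(2000):
            level, path = assign_acuity_and_path({AcuityLevel.AL3: 1.0}, PATH_TABLE, rng)
            assert level is AcuityLevel.AL3
            counts[path] += 1
        assert counts[Path.P1] == 0 and counts[Path.P4] == 0
        assert counts[Path.P2] / 2000 == pytest.approx(0.76, abs=0.05)

    def test_point_mass(self, rng):
        table = dict(PATH_TABLE)
        table[AcuityLevel.AL5] = {Path.P1: 1.0}
        for _ in range(20):
            assert assign_acuity_and_path({AcuityLevel.AL5: 1.0}, table, rng) == (
                AcuityLevel.AL5,
                Path.P1,
            )

    def test_normal_mix_path_frequencies(self, rng):
        # joint law of (acuity, path) marginalised over acuity
        n = 200_000
        _, path = _assign_vector(n, NORMAL_MIX, PATH_TABLE, rng)
        freq = np.bincount(path, minlength=4) / n
        expected = [0.045, 0.6534, 0.2016, 0.10]
        for f, e in zip(freq, expected):
            assert f == pytest.approx(e, abs=4 * math.sqrt(e * (1 - e) / n))

    def test_mix_must_sum_to_one(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            assign_acuity_and_path({AcuityLevel.AL3: 0.9}, PATH_TABLE, rng)

    def test_negative_proportion_rejected(self, rng):
        bad = {AcuityLevel.AL3: 1.2, AcuityLevel.AL4: -0.2}
        with pytest.raises(ValueError, match="negative"):
            assign_acuity_and_path(bad, PATH_TABLE, rng)

    def test_al12_must_map_to_p4(self, rng):
        table = {k: dict(v) for k, v in PATH_TABLE.items()}
        table[AcuityLevel.AL12] = {Path.P1: 1.0}
        with pytest.raises(ValueError):
            assign_acuity_and_path(NORMAL_MIX, table, rng)


# ---------------------------------------------------------------------------
# Replication simulation


def path_timestamp_keys(path):
    keys = []
    for kind in PATH_STATIONS[path]:
        keys += [f"{kind.value}_queued", f"{kind.value}_start", f"{kind.value}_end"]
    return keys


class TestSimulateReplication:
    def test_unbounded_capacities_wait_equals_own_triage_duration(self, rng):
        scenario = make_scenario(
            daily_total=200.0,
            stations=capacities(triage=None, consultation=None, lab=None),
        )
        for p in simulate_replication(scenario, rng):
            if p.path is Path.P4 or p.censored:
                continue
            ts = p.timestamps
            assert ts["triage_start"] == ts["t0_arrival"]  # no triage queue
            assert ts["t3_treatment_start"] == ts["triage_end"]  # no consult queue
            assert waiting_time(p) == pytest.approx(ts["triage_end"] - ts["triage_start"])

    def test_hand_traced_two_patient_schedule(self, rng):
        # fixed triage 3 / consultation 50, triage 1 server, consult 13:
        # arrival 0 -> triage [0,3], treatment at 3 (wait 3)
        # arrival 1 -> triage [3,6], treatment at 6 (wait 5)
        scenario = FixedArrivalScenario(
            [0.0, 1.0],
            normal_mix={AcuityLevel.AL5: 1.0},
            seismic_mix={AcuityLevel.AL5: 1.0},
            path_table={**PATH_TABLE, AcuityLevel.AL5: {Path.P1: 1.0}},
            service_times=fixed_service(triage=3.0, consultation=50.0),
            stations=capacities(triage=1, consultation=13),
        )
        a, b = simulate_replication(scenario, rng)
        assert waiting_time(a) == 3.0 and waiting_time(b) == 5.0
        assert b.timestamps["triage_start"] == 3.0
        assert b.timestamps["triage_end"] == 6.0
        assert a.timestamps["depart"] == 53.0 and b.timestamps["depart"] == 56.0

    def test_hand_traced_single_consultation_server(self, rng):
        # with one consultation server the consult queue dominates:
        # treatments start at 3, 53, 103
        scenario = FixedArrivalScenario(
            [0.0, 1.0, 2.0],
            normal_mix={AcuityLevel.AL5: 1.0},
            seismic_mix={AcuityLevel.AL5: 1.0},
            path_table={**PATH_TABLE, AcuityLevel.AL5: {Path.P1: 1.0}},
            service_times=fixed_service(triage=3.0, consultation=50.0),
            stations=capacities(triage=1, consultation=1),
        )
        recs = simulate_replication(scenario, rng)
        assert [r.timestamps["t3_treatment_start"] for r in recs] == [3.0, 53.0, 103.0]

    def test_conservation_and_path_membership(self, rng):
        scenario = make_scenario(n_days=2, daily_total=150.0, mix=NORMAL_MIX)
        recs = simulate_replication(scenario, rng)
        by_path = {p: sum(r.path is p for r in recs) for p in Path}
        assert sum(by_path.values()) == len(recs)
        for r in recs:
            assert r.acuity in {
                Path.P1: {AcuityLevel.AL5},
                Path.P2: {AcuityLevel.AL3, AcuityLevel.AL4, AcuityLevel.AL5},
                Path.P3: {AcuityLevel.AL3, AcuityLevel.AL4},
                Path.P4: {AcuityLevel.AL12},
            }[r.path]
            if r.path is Path.P4:
                assert set(r.timestamps) == {"t0_arrival"}  # diverted at generation

    def test_timestamps_monotone_along_path(self, rng):
        scenario = make_scenario(n_days=2, daily_total=300.0, mix=NORMAL_MIX)
        for r in simulate_replication(scenario, rng):
            seq = [r.timestamps[k] for k in path_timestamp_keys(r.path)]
            assert all(a <= b for a, b in zip(seq, seq[1:]))
            if "t3_treatment_start" in r.timestamps:
                assert r.timestamps["t3_treatment_start"] >= r.timestamps["t0_arrival"]

    @pytest.mark.parametrize("kind, cap", [(ServiceKind.TRIAGE, 1), (ServiceKind.CONSULTATION, 4)])
    def test_capacity_never_exceeded(self, rng, kind, cap):
        scenario = make_scenario(
            daily_total=400.0, mix=NORMAL_MIX, stations=capacities(consultation=4)
        )
        events = []
        for r in simulate_replication(scenario, rng):
            if f"{kind.value}_start" in r.timestamps:
                events.append((r.timestamps[f"{kind.value}_start"], 1))
                events.append((r.timestamps[f"{kind.value}_end"], -1))
        events.sort(key=lambda e: (e[0], e[1]))  # end before start on ties
        load = peak = 0
        for _, delta in events:
            load += delta
            peak = max(peak, load)
        assert peak <= cap

    def test_fifo_shared_queue_symmetric_across_levels(self):
        # with no priority the waiting-time law is level-independent
        waits = {l: [] for l in (AcuityLevel.AL3, AcuityLevel.AL4, AcuityLevel.AL5)}
        scenario = make_scenario(n_days=4, daily_total=278.0, mix=NORMAL_MIX)
        for rep in range(10):
            recs = simulate_replication(scenario, np.random.default_rng(rep))
            for r in recs:
                if r.treated:
                    waits[r.acuity].append(waiting_time(r))
        means = [np.mean(waits[l]) for l in waits]
        assert max(means) - min(means) < 0.15 * np.mean(means)

    def test_censoring_flagged_not_silent(self, rng):
        # one consult server and a flood of patients: most remain untreated
        scenario = FixedArrivalScenario(
            np.linspace(0.0, 1400.0, 200),
            normal_mix={AcuityLevel.AL5: 1.0},
            seismic_mix={AcuityLevel.AL5: 1.0},
            path_table={**PATH_TABLE, AcuityLevel.AL5: {Path.P1: 1.0}},
            service_times=fixed_service(triage=1.0, consultation=100.0),
            stations=capacities(triage=1, consultation=1),
        )
        with pytest.warns(UserWarning, match="untreated at horizon"):
            recs = simulate_replication(scenario, rng)
        censored = [r for r in recs if r.censored]
        assert len(censored) > 100
        with pytest.raises(ValueError, match="censored"):
            waiting_time(censored[0])


class TestWaitingTime:
    def test_simple_difference(self):
        p = Patient(0, 0, AcuityLevel.AL3, Path.P2, 100.0, 0,
                    {"t0_arrival": 100.0, "t3_treatment_start": 109.0})
        assert waiting_time(p) == 9.0
        p.timestamps["t3_treatment_start"] = 100.0
        assert waiting_time(p) == 0.0

    def test_untreated_patient_raises(self):
        p = Patient(0, 0, AcuityLevel.AL12, Path.P4, 5.0, 0, {"t0_arrival": 5.0})
        with pytest.raises(ValueError, match="never treated"):
            waiting_time(p)


class TestErlangC:
    @staticmethod
    def erlang_c_wq(lam, mu, c):
        """Mean queue wait of M/M/c (independent closed-form oracle)."""
        a = lam / mu
        terms = [a**k / math.factorial(k) for k in range(c)]
        last = a**c / math.factorial(c) * c / (c - a)
        p_wait = last / (sum(terms) + last)
        return p_wait / (c * mu - lam)

    def test_exponential_limit_matches_erlang_c(self):
        # Poisson arrivals + gamma(1, mean) = exponential service at a
        # 3-server triage station (rho = 0.7); a few independent runs of
        # ~1e5 simulated minutes each tame queue autocorrelation
        mean_service, cap, days = 10.0, 3, 70
        daily = 302.4  # lambda = 0.21/min
        cfg = ServiceTimeConfig.default()
        cfg[ServiceKind.TRIAGE] = ServiceTime("gamma", (1.0, mean_service))
        scenario = make_scenario(
            n_days=days,
            daily_total=daily,
            stations=capacities(triage=cap, consultation=None, lab=None),
            service_times=cfg,
        )
        waits = []
        for sub in range(4):
            recs = simulate_replication(scenario, np.random.default_rng([0, sub]))
            waits += [
                r.timestamps["triage_start"] - r.timestamps["t0_arrival"]
                for r in recs
                if "triage_start" in r.timestamps and r.arrival_day >= 2  # burn-in
            ]
        expected = self.erlang_c_wq(daily / 1440.0, 1 / mean_service, cap)
        assert np.mean(waits) == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# FIFO station solver properties (vs a brute-force event-driven oracle)


def brute_force_fifo(entry, service, capacity):
    """Naive event-driven FIFO multi-server simulation (test oracle)."""
    free = [0.0] * capacity
    starts = []
    for e, s in zip(entry, service):
        i = min(range(capacity), key=lambda j: free[j])
        start = max(e, free[i])
        free[i] = start + s
        starts.append(start)
    return starts


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(0, 1000, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
        ),
        min_size=1,
        max_size=40,
    ),
    capacity=st.integers(1, 5),
)
def test_fifo_station_matches_brute_force(data, capacity):
    entry = np.sort(np.array([d[0] for d in data]))
    service = np.array([d[1] for d in data])
    got = _fifo_station(entry, service, capacity)
    want = brute_force_fifo(entry, service, capacity)
    assert np.allclose(got, want)
    assert (got >= entry).all()  # service never starts before queue entry


# ---------------------------------------------------------------------------
# Event-log round trip


def test_event_log_round_trip(tmp_path, rng):
    scenario = make_scenario(daily_total=80.0, mix=NORMAL_MIX)
    recs = simulate_replication(scenario, rng)
    path = tmp_path / "events.csv"
    export_event_log(recs, path)
    back = read_event_log(path)
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert (a.id, a.acuity, a.path, a.arrival_day, a.censored) == (
            b.id,
            b.acuity,
            b.path,
            b.arrival_day,
            b.censored,
        )
        assert b.timestamps["t0_arrival"] == a.timestamps["t0_arrival"]
        if a.treated:
            assert waiting_time(b) == waiting_time(a)


def test_read_event_log_missing_columns(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("replication,patient_id\n0,1\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_event_log(p)


def test_advised_max_wait_ordering():
    al3, al4, al5 = AcuityLevel.AL3, AcuityLevel.AL4, AcuityLevel.AL5
    assert al3.advised_max_wait < al4.advised_max_wait < al5.advised_max_wait
    with pytest.raises(ValueError):
        AcuityLevel.AL12.advised_max_wait
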