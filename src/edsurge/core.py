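"""Patient-flow model of a general emergency responsibility hospital.

Patients arriving at the emergency department are triaged into acuity
levels (AL1/2 most urgent .. AL5 least urgent) and routed along one of
four fixed paths through capacity-limited service stations:

* Path 1: triage -> consultation -> depart            (AL5 only)
* Path 2: triage -> consultation -> observation        (AL3/AL4/AL5)
* Path 3: triage -> consultation -> lab -> observation (AL3/AL4)
* Path 4: diverted at arrival to a higher-ranked hospital (AL1/AL2);
  consumes no resources of the modelled hospital.

Each station is a FIFO multi-server queue: at most ``capacity`` patients
are in service simultaneously, waiting patients are served in order of
arrival at the station's queue, and the earliest-free server is taken.
Because the paths are feed-forward (triage, consultation, lab,
observation are always visited in that order and never revisited), the
network can be solved station by station: a station's queue-entry times
are fully determined by the completion times of the previous station, so
processing stations in topological order reproduces exactly the event
schedule of a global event-driven simulation with stable (arrival-order)
tie-breaking.

Service durations are random, drawn per patient from per-station
distributions (gamma for triage, triangular elsewhere by default).
Waiting time is the door-to-doctor time: arrival (t0) to treatment start
(t3), i.e. triage queue + triage service + consultation queue.
"""

from __future__ import annotations

import csv
import enum
import heapq
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AcuityLevel",
    "ServiceKind",
    "Path",
    "PATH_STATIONS",
    "PATH_MEMBERSHIP",
    "ServiceTime",
    "ServiceTimeConfig",
    "StationSet",
    "Patient",
    "sample_service_time",
    "assign_acuity_and_path",
    "simulate_replication",
    "waiting_time",
    "export_event_log",
    "read_event_log",
]

MINUTES_PER_DAY = 1440.0


class AcuityLevel(enum.Enum):
    """Five-level triage category, with AL1 and AL2 pooled.

    The modelled hospital treats the non-urgent levels AL3-AL5; AL1/AL2
    patients are diverted to advanced/intermediate hospitals.
    """

    AL12 = "AL12"
    AL3 = "AL3"
    AL4 = "AL4"
    AL5 = "AL5"

    @property
    def advised_max_wait(self) -> float:
        """Regulatory maximum door-to-doctor time in minutes.

        Defined for AL3 (30), AL4 (60) and AL5 (120); the pooled urgent
        level AL12 is out of the modelled hospital's scope and raises.
        """
        try:
            return _ADVISED_MAX_WAIT[self]
        except KeyError:
            raise ValueError(
                f"advised maximum waiting time is not defined for {self.name}"
            ) from None


_ADVISED_MAX_WAIT: dict[AcuityLevel, float] = {
    AcuityLevel.AL3: 30.0,
    AcuityLevel.AL4: 60.0,
    AcuityLevel.AL5: 120.0,
}

#: The three acuity levels treated in the modelled hospital.
TREATED_LEVELS = (AcuityLevel.AL3, AcuityLevel.AL4, AcuityLevel.AL5)


class ServiceKind(enum.Enum):
    TRIAGE = "triage"
    CONSULTATION = "consultation"
    OBSERVATION = "observation"
    LAB = "lab"


class Path(enum.Enum):
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"


#: Station sequence of each path, in visit order.
PATH_STATIONS: dict[Path, tuple[ServiceKind, ...]] = {
    Path.P1: (ServiceKind.TRIAGE, ServiceKind.CONSULTATION),
    Path.P2: (ServiceKind.TRIAGE, ServiceKind.CONSULTATION, ServiceKind.OBSERVATION),
    Path.P3: (
        ServiceKind.TRIAGE,
        ServiceKind.CONSULTATION,
        ServiceKind.LAB,
        ServiceKind.OBSERVATION,
    ),
    Path.P4: (),
}

#: Which acuity levels may take which path.
PATH_MEMBERSHIP: dict[Path, frozenset[AcuityLevel]] = {
    Path.P1: frozenset({AcuityLevel.AL5}),
    Path.P2: frozenset({AcuityLevel.AL3, AcuityLevel.AL4, AcuityLevel.AL5}),
    Path.P3: frozenset({AcuityLevel.AL3, AcuityLevel.AL4}),
    Path.P4: frozenset({AcuityLevel.AL12}),
}


@dataclass(frozen=True)
class ServiceTime:
    """Service-duration distribution for one station.

    Supported families (parameters in minutes):

    * ``gamma``: shape, scale (mean = shape * scale)
    * ``triangular``: min, mode, max
    * ``fixed``: a single constant duration (degenerate distribution,
      mostly useful for constructing hand-checkable schedules)
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.params)
        object.__setattr__(self, "params", p)
        if self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"gamma requires positive (shape, scale); got {p}")
        elif self.family == "triangular":
            if len(p) != 3 or not (0 <= p[0] <= p[1] <= p[2]) or p[0] == p[2]:
                raise ValueError(
                    f"triangular requires 0 <= min <= mode <= max, min < max; got {p}"
                )
        elif self.family == "fixed":
            if len(p) != 1 or p[0] < 0:
                raise ValueError(f"fixed requires one non-negative value; got {p}")
        else:
            raise ValueError(f"unknown service-time family {self.family!r}")

    @property
    def mean(self) -> float:
        if self.family == "gamma":
            return self.params[0] * self.params[1]
        if self.family == "triangular":
            return sum(self.params) / 3.0
        return self.params[0]

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "gamma":
            return rng.gamma(self.params[0], self.params[1], size=size)
        if self.family == "triangular":
            return rng.triangular(*self.params, size=size)
        if size is None:
            return self.params[0]
        return np.full(size, self.params[0])


class ServiceTimeConfig(dict):
    """Mapping ``ServiceKind -> ServiceTime`` with the model defaults."""

    @classmethod
    def default(cls) -> "ServiceTimeConfig":
        return cls(
            {
                ServiceKind.TRIAGE: ServiceTime("gamma", (4.5, 0.7)),
                ServiceKind.CONSULTATION: ServiceTime("triangular", (15, 45, 90)),
                ServiceKind.OBSERVATION: ServiceTime("triangular", (0, 15, 60)),
                ServiceKind.LAB: ServiceTime("triangular", (30, 75, 120)),
            }
        )


@dataclass(frozen=True)
class StationSet:
    """Per-station server counts; ``None`` means unbounded.

    A "server" is one resource unit: the aggregate of all labour and
    devices needed to serve one patient at that station, so capacity is
    the number of patients that can be in service simultaneously.
    """

    capacities: Mapping[ServiceKind, int | None]

    def __post_init__(self) -> None:
        caps = dict(self.capacities)
        for kind in ServiceKind:
            if kind not in caps:
                raise ValueError(f"missing capacity for station {kind.value!r}")
            c = caps[kind]
            if c is not None and (int(c) != c or c < 1):
                raise ValueError(
                    f"capacity for {kind.value!r} must be a positive integer "
                    f"or None (unbounded); got {c!r}"
                )
        object.__setattr__(self, "capacities", caps)

    def __getitem__(self, kind: ServiceKind) -> int | None:
        return self.capacities[kind]

    @classmethod
    def default(cls) -> "StationSet":
        return cls(
            {
                ServiceKind.TRIAGE: 1,
                ServiceKind.CONSULTATION: 13,
                ServiceKind.LAB: 6,
                ServiceKind.OBSERVATION: None,
            }
        )


@dataclass(slots=True)
class Patient:
    """One simulated individual and their event log.

    ``timestamps`` maps event names to minutes since simulation start:
    ``t0_arrival`` always; for patients entering the modelled hospital
    also ``<station>_queued`` / ``<station>_start`` / ``<station>_end``
    for each visited station, ``t3_treatment_start`` (an alias of
    ``consultation_start``, the door-to-doctor endpoint) and ``depart``.
    Diverted (Path 4) patients carry only ``t0_arrival``.
    """

    id: int
    replication: int
    acuity: AcuityLevel
    path: Path
    arrival_time: float
    arrival_day: int
    timestamps: dict[str, float] = field(default_factory=dict)
    censored: bool = False

    @property
    def treated(self) -> bool:
        return "t3_treatment_start" in self.timestamps and not self.censored


def sample_service_time(
    kind: ServiceKind, config: Mapping[ServiceKind, ServiceTime], rng: np.random.Generator
) -> float:
    """Draw one service duration (minutes) for a station."""
    try:
        dist = config[kind]
    except KeyError:
        raise ValueError(f"no service-time distribution configured for {kind!r}") from None
    return float(dist.sample(rng))


def _validate_probs(name: str, probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} contains a negative proportion: {list(p)}")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions must sum to 1; got sum {p.sum():.12g}")
    return p


def validate_path_table(
    path_table: Mapping[AcuityLevel, Mapping[Path, float]]
) -> None:
    """Check each acuity's path row sums to 1 and respects path membership."""
    for level in AcuityLevel:
        if level not in path_table:
            raise ValueError(f"path table is missing a row for {level.name}")
        row = path_table[level]
        _validate_probs(f"path row for {level.name}", [row.get(p, 0.0) for p in Path])
        for p in Path:
            if row.get(p, 0.0) > 0 and level not in PATH_MEMBERSHIP[p]:
                raise ValueError(
                    f"{level.name} cannot take {p.name} "
                    f"(allowed: {sorted(l.name for l in PATH_MEMBERSHIP[p])})"
                )
    if abs(path_table[AcuityLevel.AL12].get(Path.P4, 0.0) - 1.0) > 1e-9:
        raise ValueError("AL12 patients must always be diverted to P4")


def assign_acuity_and_path(
    mix: Mapping[AcuityLevel, float],
    path_table: Mapping[AcuityLevel, Mapping[Path, float]],
    rng: np.random.Generator,
) -> tuple[AcuityLevel, Path]:
    """Draw one (acuity, path) pair with joint law ``mix x path_table``."""
    levels = list(AcuityLevel)
    mix_p = _validate_probs("acuity mix", [mix.get(l, 0.0) for l in levels])
    validate_path_table(path_table)
    level = levels[rng.choice(len(levels), p=mix_p)]
    paths = list(Path)
    row = _validate_probs(
        f"path row for {level.name}", [path_table[level].get(p, 0.0) for p in paths]
    )
    return level, paths[rng.choice(len(paths), p=row)]


# ---------------------------------------------------------------------------
# FIFO multi-server station solver


def _fifo_station(
    entry: np.ndarray, service: np.ndarray, capacity: int | None
) -> np.ndarray:
    """Service start times for a FIFO station, given queue-entry times.

    ``entry`` must be in queue order (ties resolved by position); the
    patient at the head of the queue takes the earliest-free server.
    """
    if capacity is None:
        return entry.copy()
    n = len(entry)
    if n == 0:
        return np.empty(0)
    if capacity == 1:
        # scalar recursion, exact (no heap bookkeeping needed)
        start = np.empty(n)
        prev_end = 0.0
        ent = entry.tolist()
        svc = service.tolist()
        for i in range(n):
            s = prev_end if prev_end > ent[i] else ent[i]
            start[i] = s
            prev_end = s + svc[i]
        return start
    free = [0.0] * capacity
    start = np.empty(n)
    ent = entry.tolist()
    svc = service.tolist()
    for i in range(n):
        t = heapq.heappop(free)
        s = t if t > ent[i] else ent[i]
        start[i] = s
        heapq.heappush(free, s + svc[i])
    return start


# ---------------------------------------------------------------------------
# Replication simulation

_LEVEL_ORDER = list(AcuityLevel)
_PATH_ORDER = list(Path)


def _assign_vector(
    n: int,
    mix: Mapping[AcuityLevel, float],
    path_table: Mapping[AcuityLevel, Mapping[Path, float]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (acuity, path) assignment; returns integer codes."""
    mix_p = _validate_probs("acuity mix", [mix.get(l, 0.0) for l in _LEVEL_ORDER])
    acuity = rng.choice(len(_LEVEL_ORDER), size=n, p=mix_p)
    path = np.empty(n, dtype=np.int64)
    for li, level in enumerate(_LEVEL_ORDER):
        m = acuity == li
        k = int(m.sum())
        if k == 0:
            continue
        row = _validate_probs(
            f"path row for {level.name}",
            [path_table[level].get(p, 0.0) for p in _PATH_ORDER],
        )
        path[m] = rng.choice(len(_PATH_ORDER), size=k, p=row)
    return acuity, path


def _simulate_arrays(scenario, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Run one replication, returning the event log as flat arrays.

    Times are minutes since simulation start; NaN marks events a patient
    does not undergo (e.g. lab times for Path 2).
    """
    validate_path_table(scenario.path_table)
    t0, day = scenario.sample_arrivals(rng)
    n = len(t0)
    acuity = np.empty(n, dtype=np.int64)
    path = np.empty(n, dtype=np.int64)
    phases = scenario.profile.phases
    # assignment is per-phase because the acuity mix shifts during the surge
    phase_of_patient = np.asarray([0 if phases[d] == "busy" else 1 for d in day])
    for code, mix in ((0, scenario.seismic_mix), (1, scenario.normal_mix)):
        m = phase_of_patient == code
        k = int(m.sum())
        if k:
            a, p = _assign_vector(k, mix, scenario.path_table, rng)
            acuity[m], path[m] = a, p

    cols = {
        "t0_arrival": t0,
        "arrival_day": day.astype(float),
        "acuity": acuity.astype(float),
        "path": path.astype(float),
    }
    for kind in ServiceKind:
        for ev in ("queued", "start", "end"):
            cols[f"{kind.value}_{ev}"] = np.full(n, np.nan)
    cols["depart"] = np.full(n, np.nan)

    p4 = _PATH_ORDER.index(Path.P4)
    inside = path != p4  # P4 patients are diverted at generation
    stations = scenario.stations
    svc_cfg = scenario.service_times

    def run_station(kind: ServiceKind, idx: np.ndarray, entry: np.ndarray) -> np.ndarray:
        """Solve one station for patients ``idx`` entering its queue at ``entry``."""
        if len(idx) == 0:
            return entry
        # FIFO: queue order is entry-time order, arrival index breaks ties
        order = np.lexsort((idx, entry))
        service = np.asarray(svc_cfg[kind].sample(rng, size=len(idx)), dtype=float)
        start = np.empty(len(idx))
        start[order] = _fifo_station(entry[order], service[order], stations[kind])
        cols[f"{kind.value}_queued"][idx] = entry
        cols[f"{kind.value}_start"][idx] = start
        cols[f"{kind.value}_end"][idx] = start + service
        return start + service

    idx_in = np.flatnonzero(inside)
    triage_end = run_station(ServiceKind.TRIAGE, idx_in, t0[idx_in])
    consult_end = run_station(ServiceKind.CONSULTATION, idx_in, triage_end)

    p_of = path[idx_in]
    p1 = _PATH_ORDER.index(Path.P1)
    p3 = _PATH_ORDER.index(Path.P3)
    m_lab = p_of == p3
    lab_end = run_station(ServiceKind.LAB, idx_in[m_lab], consult_end[m_lab])

    m_obs = p_of != p1  # P2 and P3 rest under observation before departing
    obs_entry = consult_end.copy()
    obs_entry[m_lab] = lab_end
    run_station(ServiceKind.OBSERVATION, idx_in[m_obs], obs_entry[m_obs])

    depart = cols["depart"]
    depart[idx_in[p_of == p1]] = cols["consultation_end"][idx_in[p_of == p1]]
    depart[idx_in[m_obs]] = cols["observation_end"][idx_in[m_obs]]

    horizon = scenario.horizon_days * MINUTES_PER_DAY
    t3 = cols["consultation_start"]
    censored = inside & (t3 >= horizon)
    cols["censored"] = censored.astype(float)
    return cols


#: Censored fractions above this trigger a warning: the horizon should be
#: long enough that end-of-run truncation is negligible.
CENSOR_WARN_FRACTION = 0.001


def warn_if_censored(n_censored: int, n_inside: int) -> None:
    if n_inside and n_censored / n_inside > CENSOR_WARN_FRACTION:
        warnings.warn(
            f"{n_censored}/{n_inside} patients ({n_censored / n_inside:.2%}) "
            "still untreated at horizon end; consider a longer horizon",
            stacklevel=3,
        )


def _records_from_arrays(cols: Mapping[str, np.ndarray], replication: int) -> list[Patient]:
    n = len(cols["t0_arrival"])
    out: list[Patient] = []
    event_keys = [k for k in cols if k.endswith(("_queued", "_start", "_end"))] + ["depart"]
    for i in range(n):
        ts = {"t0_arrival": float(cols["t0_arrival"][i])}
        for k in event_keys:
            v = cols[k][i]
            if not np.isnan(v):
                ts[k] = float(v)
        if "consultation_start" in ts:
            ts["t3_treatment_start"] = ts["consultation_start"]
        out.append(
            Patient(
                id=i,
                replication=replication,
                acuity=_LEVEL_ORDER[int(cols["acuity"][i])],
                path=_PATH_ORDER[int(cols["path"][i])],
                arrival_time=float(cols["t0_arrival"][i]),
                arrival_day=int(cols["arrival_day"][i]),
                timestamps=ts,
                censored=bool(cols["censored"][i]),
            )
        )
    return out


def simulate_replication(
    scenario, rng: np.random.Generator, replication: int = 0
) -> list[Patient]:
    """Simulate one replication of a scenario and return all patient records.

    Patients are generated over the scenario's arrival profile, assigned
    an acuity level and path from the day's phase mix, and pushed through
    the FIFO station network. Every patient carries a complete ordered
    timestamp log; patients whose treatment has not started by the end of
    the horizon are flagged ``censored`` (a warning is emitted if they
    exceed 0.1% of those entering the hospital).
    """
    cols = _simulate_arrays(scenario, rng)
    n_inside = int((cols["path"] != _PATH_ORDER.index(Path.P4)).sum())
    warn_if_censored(int(cols["censored"].sum()), n_inside)
    return _records_from_arrays(cols, replication)


def waiting_time(patient: Patient) -> float:
    """Door-to-doctor time (minutes): treatment start minus arrival.

    Covers queuing for triage, triage itself and queuing for
    consultation. Raises for diverted or censored patients rather than
    returning a misleading zero.
    """
    if patient.censored:
        raise ValueError(f"patient {patient.id} is censored (untreated at horizon end)")
    try:
        t3 = patient.timestamps["t3_treatment_start"]
    except KeyError:
        raise ValueError(f"patient {patient.id} was never treated (path {patient.path.name})") from None
    return t3 - patient.timestamps["t0_arrival"]


# ---------------------------------------------------------------------------
# Event-log I/O

_LOG_FIELDS = [
    "replication",
    "patient_id",
    "acuity",
    "path",
    "t0_arrival",
    "t3_treatment_start",
    "depart_time",
    "arrival_day",
    "censored_flag",
]


def export_event_log(records: Iterable[Patient], path) -> None:
    """Write patient records to CSV (times in minutes, empty if absent)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LOG_FIELDS)
        for p in records:
            w.writerow(
                [
                    p.replication,
                    p.id,
                    p.acuity.value,
                    p.path.value,
                    repr(p.arrival_time),
                    repr(p.timestamps["t3_treatment_start"])
                    if "t3_treatment_start" in p.timestamps
                    else "",
                    repr(p.timestamps["depart"]) if "depart" in p.timestamps else "",
                    p.arrival_day,
                    int(p.censored),
                ]
            )


def read_event_log(path) -> list[Patient]:
    """Read a patient event-log CSV written by :func:`export_event_log`.

    Also accepts externally produced logs with the same columns, so real
    or third-party event data can be scored with the package's metrics.
    """
    out: list[Patient] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_LOG_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"event log is missing columns: {sorted(missing)}")
        for row in reader:
            ts = {"t0_arrival": float(row["t0_arrival"])}
            if row["t3_treatment_start"]:
                ts["t3_treatment_start"] = float(row["t3_treatment_start"])
            if row["depart_time"]:
                ts["depart"] = float(row["depart_time"])
            out.append(
                Patient(
                    id=int(row["patient_id"]),
                    replication=int(row["replication"]),
                    acuity=AcuityLevel(row["acuity"]),
                    path=Path(row["path"]),
                    arrival_time=float(row["t0_arrival"]),
                    arrival_day=int(row["arrival_day"]),
                    timestamps=ts,
                    censored=bool(int(row["censored_flag"])),
                )
            )
    return out
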