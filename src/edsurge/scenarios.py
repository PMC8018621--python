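"""Arrival profiles and scenario configurations.

The study conditions are a normal state (constant 278 AL3-AL5 visits per
day) and four seismic surge scenarios named by their patient growth
ratio P, the ratio of total patient visits during the four-day busy
phase to the normal volume over the same duration: GR1 (P=1.4), GR2
(P=1.6), GR3 (P=1.9) and GR4 (P=2.3). Every surge scenario opens with
two pre-earthquake lead days, followed by the four busy days, then
recovery days padding the horizon to 12-20 days.

Two acuity mixes apply: the normal mix (AL3 52%, AL4 32%, AL5 6%,
AL1/AL2 10%) on lead/recovery days and the seismic mix (50/30/3/17%) on
busy days, reflecting the higher share of urgent casualties after an
earthquake. Daily totals are expressed as AL3-AL5 arrivals at the
modelled hospital; the diverted AL1/AL2 share rides on top via the
day's mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    MINUTES_PER_DAY,
    AcuityLevel,
    Path,
    ServiceKind,
    ServiceTime,
    ServiceTimeConfig,
    StationSet,
    validate_path_table,
)

__all__ = [
    "NORMAL_MIX",
    "SEISMIC_MIX",
    "PATH_TABLE",
    "NORMAL_DAILY_TOTAL",
    "GR1_BUSY_TOTALS",
    "GR2_BUSY_TOTALS",
    "BUILTIN_GROWTH_RATIOS",
    "ArrivalProfile",
    "ScenarioConfig",
    "normal_profile",
    "seismic_profile",
    "generate_arrival_times",
    "build_scenario",
    "load_scenario",
]

NORMAL_MIX: dict[AcuityLevel, float] = {
    AcuityLevel.AL3: 0.52,
    AcuityLevel.AL4: 0.32,
    AcuityLevel.AL5: 0.06,
    AcuityLevel.AL12: 0.10,
}
SEISMIC_MIX: dict[AcuityLevel, float] = {
    AcuityLevel.AL3: 0.50,
    AcuityLevel.AL4: 0.30,
    AcuityLevel.AL5: 0.03,
    AcuityLevel.AL12: 0.17,
}
PATH_TABLE: dict[AcuityLevel, dict[Path, float]] = {
    AcuityLevel.AL3: {Path.P2: 0.76, Path.P3: 0.24},
    AcuityLevel.AL4: {Path.P2: 0.76, Path.P3: 0.24},
    AcuityLevel.AL5: {Path.P1: 0.75, Path.P2: 0.25},
    AcuityLevel.AL12: {Path.P4: 1.0},
}

#: Expected AL3-AL5 arrivals per normal day at the modelled hospital.
NORMAL_DAILY_TOTAL = 278.0

#: Busy-day AL3-AL5 totals of the two scenarios published day by day.
GR1_BUSY_TOTALS = (366.0, 411.0, 334.0, 284.0)
GR2_BUSY_TOTALS = (449.0, 509.0, 371.0, 298.0)

BUILTIN_GROWTH_RATIOS = {"GR1": 1.4, "GR2": 1.6, "GR3": 1.9, "GR4": 2.3}

LEAD_DAYS = 2
BUSY_DAYS = 4
MIN_HORIZON, MAX_HORIZON = 12, 20


def default_horizon(growth_ratio: float) -> int:
    """Horizon long enough to show the full recovery curve."""
    if growth_ratio <= 1.6:
        return 12
    if growth_ratio <= 2.0:
        return 16
    return 20


@dataclass(frozen=True)
class ArrivalProfile:
    """Per-day expected AL3-AL5 arrival counts with phase labels.

    ``phases[d]`` is one of ``lead``/``busy``/``recovery`` and selects
    the day's acuity mix. ``intraday_weights`` optionally shapes the
    within-day intensity over 24 hourly bins (default: uniform).
    """

    daily_total: tuple[float, ...]
    phases: tuple[str, ...]
    intraday_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        totals = tuple(float(x) for x in self.daily_total)
        phases = tuple(self.phases)
        object.__setattr__(self, "daily_total", totals)
        object.__setattr__(self, "phases", phases)
        if len(totals) != len(phases):
            raise ValueError("daily_total and phases must have equal length")
        if any(x < 0 for x in totals):
            raise ValueError("expected arrival counts must be >= 0")
        if any(p not in ("lead", "busy", "recovery") for p in phases):
            raise ValueError(f"unknown phase label in {phases}")
        if "busy" in phases:
            n_busy = phases.count("busy")
            if phases[:LEAD_DAYS] != ("lead",) * LEAD_DAYS or phases[
                LEAD_DAYS : LEAD_DAYS + BUSY_DAYS
            ] != ("busy",) * BUSY_DAYS or n_busy != BUSY_DAYS:
                raise ValueError(
                    f"a surge profile needs exactly {LEAD_DAYS} lead days followed "
                    f"by exactly {BUSY_DAYS} busy days"
                )
            if any(p != "recovery" for p in phases[LEAD_DAYS + BUSY_DAYS :]):
                raise ValueError("days after the busy phase must be 'recovery'")
            if not MIN_HORIZON <= len(phases) <= MAX_HORIZON:
                raise ValueError(
                    f"surge horizon must span {MIN_HORIZON}-{MAX_HORIZON} days; "
                    f"got {len(phases)}"
                )
        if self.intraday_weights is not None:
            w = tuple(float(x) for x in self.intraday_weights)
            object.__setattr__(self, "intraday_weights", w)
            if len(w) != 24 or any(x < 0 for x in w):
                raise ValueError("intraday_weights must be 24 non-negative floats")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("intraday_weights must sum to 1")

    @property
    def n_days(self) -> int:
        return len(self.daily_total)


def normal_profile(
    n_days: int = 12, daily_al345_total: float = NORMAL_DAILY_TOTAL
) -> ArrivalProfile:
    """Constant profile of ordinary demand (default 278 AL3-AL5/day)."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if daily_al345_total < 0:
        raise ValueError("daily_al345_total must be >= 0")
    return ArrivalProfile((daily_al345_total,) * n_days, ("lead",) * n_days)


def _scaled_busy_totals(growth_ratio: float, base: float) -> tuple[float, ...]:
    # The growth ratio counts all generated patients including the
    # diverted AL1/AL2 share, so scale in "generated" units and convert
    # back to AL3-AL5 arrivals with the seismic mix.
    norm_al345 = 1.0 - NORMAL_MIX[AcuityLevel.AL12]
    seis_al345 = 1.0 - SEISMIC_MIX[AcuityLevel.AL12]
    base_gen = base / norm_al345
    gr2_gen = np.asarray(GR2_BUSY_TOTALS) / seis_al345
    excess_shape = gr2_gen - base_gen
    total_excess = BUSY_DAYS * base_gen * (growth_ratio - 1.0)
    busy_gen = base_gen + total_excess * excess_shape / excess_shape.sum()
    return tuple(busy_gen * seis_al345)


def seismic_profile(
    growth_ratio: float,
    base: float = NORMAL_DAILY_TOTAL,
    horizon_days: int | None = None,
    busy_day_totals: Sequence[float] | None = None,
    intraday_weights: Sequence[float] | None = None,
) -> ArrivalProfile:
    """Surge profile: 2 lead days, 4 busy days, recovery days at base.

    Busy-day AL3-AL5 totals come from the published day-by-day counts
    for P=1.4 and P=1.6; for other ratios they are built by adding the
    total excess demand implied by P (in all-patient units, base/0.90
    per normal day) on top of the normal base, distributed across the
    four days in proportion to the P=1.6 excess-over-normal shape, then
    converted to AL3-AL5 arrivals with the seismic mix (83%).
    """
    if growth_ratio < 1.0:
        raise ValueError(f"growth_ratio must be >= 1; got {growth_ratio}")
    if horizon_days is None:
        horizon_days = default_horizon(growth_ratio)
    if busy_day_totals is not None:
        busy = tuple(float(x) for x in busy_day_totals)
        if len(busy) != BUSY_DAYS:
            raise ValueError(f"busy_day_totals must have {BUSY_DAYS} entries")
    elif math.isclose(growth_ratio, 1.0):
        busy = (float(base),) * BUSY_DAYS
    elif math.isclose(growth_ratio, 1.4) and base == NORMAL_DAILY_TOTAL:
        busy = GR1_BUSY_TOTALS
    elif math.isclose(growth_ratio, 1.6) and base == NORMAL_DAILY_TOTAL:
        busy = GR2_BUSY_TOTALS
    else:
        busy = _scaled_busy_totals(growth_ratio, base)
    n_rec = horizon_days - LEAD_DAYS - BUSY_DAYS
    if n_rec < 0:
        raise ValueError("horizon must cover the lead and busy phases")
    totals = (float(base),) * LEAD_DAYS + busy + (float(base),) * n_rec
    phases = ("lead",) * LEAD_DAYS + ("busy",) * BUSY_DAYS + ("recovery",) * n_rec
    return ArrivalProfile(
        totals,
        phases,
        tuple(intraday_weights) if intraday_weights is not None else None,
    )


def generate_arrival_times(
    profile: ArrivalProfile,
    rng: np.random.Generator,
    daily_totals: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw arrival times from a non-homogeneous Poisson process.

    The day-``d`` intensity integrates to the day-``d`` expected count
    (``profile.daily_total`` unless overridden) and is spread within the
    day by the profile's hourly weights (uniform by default). Returns
    sorted times in minutes and the matching 0-based day indices.
    """
    totals = profile.daily_total if daily_totals is None else daily_totals
    if len(totals) != profile.n_days:
        raise ValueError("daily_totals length must match the profile")
    times: list[np.ndarray] = []
    days: list[np.ndarray] = []
    for d, mean in enumerate(totals):
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        if profile.intraday_weights is None:
            within = rng.random(n) * MINUTES_PER_DAY
        else:
            hour = rng.choice(24, size=n, p=np.asarray(profile.intraday_weights))
            within = (hour + rng.random(n)) * 60.0
        times.append(d * MINUTES_PER_DAY + np.sort(within))
        days.append(np.full(n, d, dtype=np.int64))
    if not times:
        return np.empty(0), np.empty(0, dtype=np.int64)
    return np.concatenate(times), np.concatenate(days)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario."""

    name: str
    growth_ratio: float
    profile: ArrivalProfile
    normal_mix: Mapping[AcuityLevel, float] = field(
        default_factory=lambda: dict(NORMAL_MIX)
    )
    seismic_mix: Mapping[AcuityLevel, float] = field(
        default_factory=lambda: dict(SEISMIC_MIX)
    )
    path_table: Mapping[AcuityLevel, Mapping[Path, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in PATH_TABLE.items()}
    )
    stations: StationSet = field(default_factory=StationSet.default)
    service_times: ServiceTimeConfig = field(default_factory=ServiceTimeConfig.default)
    replications: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_ratio < 1.0:
            raise ValueError(f"growth_ratio must be >= 1; got {self.growth_ratio}")
        if int(self.replications) != self.replications or self.replications < 1:
            raise ValueError(f"replications must be a positive integer; got {self.replications}")
        for label, mix in (("normal_mix", self.normal_mix), ("seismic_mix", self.seismic_mix)):
            vals = [mix.get(l, 0.0) for l in AcuityLevel]
            if any(v < 0 for v in vals):
                raise ValueError(f"{label} contains a negative proportion")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{label} proportions must sum to 1; got {sum(vals):.12g}")
        validate_path_table(self.path_table)

    @property
    def horizon_days(self) -> int:
        return self.profile.n_days

    def mix_for_day(self, day: int) -> Mapping[AcuityLevel, float]:
        return self.seismic_mix if self.profile.phases[day] == "busy" else self.normal_mix

    def generated_daily_totals(self) -> np.ndarray:
        """Expected generated patients per day, including the diverted share."""
        out = np.empty(self.profile.n_days)
        for d, total in enumerate(self.profile.daily_total):
            al12 = self.mix_for_day(d).get(AcuityLevel.AL12, 0.0)
            out[d] = total / (1.0 - al12)
        return out

    def sample_arrivals(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Arrival times of all generated patients (diverted share included)."""
        return generate_arrival_times(self.profile, rng, self.generated_daily_totals())


def build_scenario(
    name: str | None = None,
    growth_ratio: float | None = None,
    horizon_days: int | None = None,
    replications: int = 300,
    seed: int = 0,
    **kwargs,
) -> ScenarioConfig:
    """Construct a built-in or custom scenario.

    ``name`` may be ``normal`` or one of ``GR1``-``GR4``; alternatively
    give ``growth_ratio`` directly (1.0 means the normal state).
    Remaining keyword arguments are forwarded to :class:`ScenarioConfig`.
    """
    if name is not None and name in BUILTIN_GROWTH_RATIOS:
        growth_ratio = growth_ratio or BUILTIN_GROWTH_RATIOS[name]
    elif name == "normal":
        growth_ratio = growth_ratio or 1.0
    if growth_ratio is None:
        raise ValueError(f"unknown scenario {name!r}; give a growth_ratio")
    base = kwargs.pop("daily_total", NORMAL_DAILY_TOTAL)
    busy = kwargs.pop("busy_day_totals", None)
    weights = kwargs.pop("intraday_weights", None)
    if math.isclose(growth_ratio, 1.0) and busy is None:
        profile = normal_profile(horizon_days or 12, base)
        if weights is not None:
            profile = replace(profile, intraday_weights=tuple(weights))
        name = name or "normal"
    else:
        profile = seismic_profile(
            growth_ratio, base, horizon_days, busy_day_totals=busy, intraday_weights=weights
        )
        name = name or f"P{growth_ratio:g}"
    return ScenarioConfig(
        name=name,
        growth_ratio=float(growth_ratio),
        profile=profile,
        replications=replications,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Config-file loading

_KNOWN_KEYS = {
    "name",
    "growth_ratio",
    "lead_days",
    "busy_days",
    "horizon_days",
    "daily_total",
    "busy_day_totals",
    "mixes",
    "path_table",
    "capacities",
    "service_times",
    "replications",
    "seed",
    "intraday_weights",
}


def _parse_mix(raw: Mapping[str, float], key: str) -> dict[AcuityLevel, float]:
    try:
        return {AcuityLevel(k): float(v) for k, v in raw.items()}
    except ValueError as exc:
        raise ValueError(f"{key}: {exc}") from None


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario from a YAML (or JSON) config file.

    Missing keys fall back to the model defaults; unknown keys are
    rejected with the offending key named.
    """
    p = FilePath(path)
    if not p.exists():
        raise FileNotFoundError(f"scenario config not found: {p}")
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"scenario config must be a mapping; got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown scenario config key(s): {sorted(unknown)}")
    if raw.get("lead_days", LEAD_DAYS) != LEAD_DAYS:
        raise ValueError(f"lead_days is fixed at {LEAD_DAYS} in this model")
    if raw.get("busy_days", BUSY_DAYS) != BUSY_DAYS:
        raise ValueError(f"busy_days is fixed at {BUSY_DAYS} in this model")

    kwargs: dict = {}
    if "mixes" in raw:
        mixes = raw["mixes"]
        extra = set(mixes) - {"normal", "seismic"}
        if extra:
            raise ValueError(f"mixes: unknown phase key(s) {sorted(extra)}")
        if "normal" in mixes:
            kwargs["normal_mix"] = _parse_mix(mixes["normal"], "mixes.normal")
        if "seismic" in mixes:
            kwargs["seismic_mix"] = _parse_mix(mixes["seismic"], "mixes.seismic")
    if "path_table" in raw:
        try:
            kwargs["path_table"] = {
                AcuityLevel(l): {Path(pp): float(v) for pp, v in row.items()}
                for l, row in raw["path_table"].items()
            }
        except ValueError as exc:
            raise ValueError(f"path_table: {exc}") from None
    if "capacities" in raw:
        caps = dict(StationSet.default().capacities)
        for k, v in raw["capacities"].items():
            try:
                kind = ServiceKind(k)
            except ValueError:
                raise ValueError(f"capacities: unknown station {k!r}") from None
            caps[kind] = None if v in (None, "inf", "unbounded") else int(v)
        kwargs["stations"] = StationSet(caps)
    if "service_times" in raw:
        cfg = ServiceTimeConfig.default()
        for k, spec in raw["service_times"].items():
            try:
                kind = ServiceKind(k)
            except ValueError:
                raise ValueError(f"service_times: unknown station {k!r}") from None
            try:
                cfg[kind] = ServiceTime(spec["family"], tuple(spec["params"]))
            except (KeyError, TypeError) as exc:
                raise ValueError(
                    f"service_times.{k}: need 'family' and 'params' ({exc})"
                ) from None
        kwargs["service_times"] = cfg

    for key in ("daily_total", "busy_day_totals", "intraday_weights"):
        if key in raw:
            kwargs[key] = raw[key]
    return build_scenario(
        name=raw.get("name"),
        growth_ratio=raw.get("growth_ratio"),
        horizon_days=raw.get("horizon_days"),
        replications=int(raw.get("replications", 300)),
        seed=int(raw.get("seed", 0)),
        **kwargs,
    )
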