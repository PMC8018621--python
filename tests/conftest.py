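import numpy as np
import pytest

from edsurge import AcuityLevel, Path, ServiceTime, ServiceTimeConfig, StationSet
from edsurge.core import ServiceKind
from edsurge.scenarios import PATH_TABLE, ScenarioConfig, normal_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20210402)


def fixed_service(triage=3.0, consultation=50.0, observation=10.0, lab=20.0):
    """Degenerate (constant) service times for hand-checkable schedules."""
    return ServiceTimeConfig(
        {
            ServiceKind.TRIAGE: ServiceTime("fixed", (triage,)),
            ServiceKind.CONSULTATION: ServiceTime("fixed", (consultation,)),
            ServiceKind.OBSERVATION: ServiceTime("fixed", (observation,)),
            ServiceKind.LAB: ServiceTime("fixed", (lab,)),
        }
    )


def capacities(triage=1, consultation=13, lab=6, observation=None):
    return StationSet(
        {
            ServiceKind.TRIAGE: triage,
            ServiceKind.CONSULTATION: consultation,
            ServiceKind.LAB: lab,
            ServiceKind.OBSERVATION: observation,
        }
    )


class FixedArrivalScenario(ScenarioConfig):
    """Scenario whose arrival times are given verbatim (no sampling)."""

    def __init__(self, arrival_times, n_days=1, daily_total=0.0, **kwargs):
        object.__setattr__(self, "_arrivals", np.asarray(arrival_times, dtype=float))
        kwargs.setdefault("name", "fixed")
        kwargs.setdefault("growth_ratio", 1.0)
        kwargs.setdefault("profile", normal_profile(n_days, daily_total))
        kwargs.setdefault("replications", 1)
        super().__init__(**kwargs)

    def sample_arrivals(self, rng):
        days = (self._arrivals // 1440).astype(np.int64)
        return self._arrivals, days


def make_scenario(n_days=1, daily_total=50.0, mix=None, **kwargs) -> ScenarioConfig:
    """Small single-phase scenario for unit tests."""
    mix = mix or {AcuityLevel.AL3: 1.0}
    kwargs.setdefault("path_table", PATH_TABLE)
    return ScenarioConfig(
        name="test",
        growth_ratio=1.0,
        profile=normal_profile(n_days, daily_total),
        normal_mix=mix,
        seismic_mix=mix,
        **kwargs,
    )
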