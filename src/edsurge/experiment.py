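"""Replicated scenario runs, sweeps over growth ratios, and output files.

An experiment runs a scenario's discrete-event simulation for a number
of independent replications (default 300, enough to level out sampling
outliers), aggregates the daily Crowdedness Index across replications,
and summarises the surge response: maximum daily CI per acuity level
and the recovery duration. Everything is reproducible from (config,
master seed): replication r uses an independent child stream spawned
from the master seed, so individual replications can be re-derived and
parallel execution cannot change results.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    TREATED_LEVELS,
    AcuityLevel,
    Patient,
    ServiceKind,
    _records_from_arrays,
    _simulate_arrays,
    warn_if_censored,
)
from .metrics import (
    DailyMetrics,
    EmpiricalFit,
    aggregate_tables,
    fit_piecewise,
    max_ci,
    recovery_duration,
)
from .scenarios import ScenarioConfig, build_scenario

__all__ = ["ExperimentResult", "run_experiment", "run_sweep", "write_outputs"]

_LEVEL_CODE = {l: i for i, l in enumerate(AcuityLevel)}


def replication_seed(master_seed: int, replication: int) -> np.random.SeedSequence:
    """Independent child stream for one replication of an experiment."""
    return np.random.SeedSequence([int(master_seed), int(replication)])


@dataclass
class ExperimentResult:
    """Aggregated outcome of a replicated scenario run."""

    scenario: ScenarioConfig
    daily: list[DailyMetrics]
    max_ci: dict[AcuityLevel, float]
    #: mean over replications of each replication's own max daily CI;
    #: reported alongside the max of the replication-averaged series.
    mean_rep_max_ci: dict[AcuityLevel, float]
    recovery_days: int
    mean_wait: dict[AcuityLevel, float]
    replications: int
    seed: int
    runtime_seconds: float
    events: list[Patient] | None = None


def _table_from_arrays(cols: Mapping[str, np.ndarray], horizon: int) -> dict[str, np.ndarray]:
    """Per-day CI table of one replication, computed from the flat arrays."""
    day = cols["arrival_day"].astype(np.int64)
    in_horizon = (day >= 0) & (day < horizon)
    arrivals = np.bincount(day[in_horizon], minlength=horizon).astype(float)

    acuity = cols["acuity"].astype(np.int64)
    t3 = cols["consultation_start"]
    treated = in_horizon & ~np.isnan(t3) & (cols["censored"] == 0)
    ci = np.full((horizon, 3), np.nan)
    n_treated = np.zeros((horizon, 3))
    wait_sum = np.zeros((horizon, 3))
    T = np.array([l.advised_max_wait for l in TREATED_LEVELS])
    for j, level in enumerate(TREATED_LEVELS):
        m = treated & (acuity == _LEVEL_CODE[level])
        d = day[m]
        w = t3[m] - cols["t0_arrival"][m]
        n_treated[:, j] = np.bincount(d, minlength=horizon)
        wait_sum[:, j] = np.bincount(d, weights=w, minlength=horizon)
    mask = n_treated > 0
    ci[mask] = (wait_sum / np.where(mask, n_treated, 1.0))[mask] / np.broadcast_to(
        T, ci.shape
    )[mask]
    return {"ci": ci, "n_treated": n_treated, "wait_sum": wait_sum, "arrivals": arrivals}


def run_experiment(
    config: ScenarioConfig,
    progress: bool = False,
    keep_events: bool = False,
) -> ExperimentResult:
    """Run ``config.replications`` independent replications and aggregate.

    Deterministic given (config, config.seed). With ``keep_events`` the
    patient records of the first replication are retained for export.
    """
    t_start = time.perf_counter()
    horizon = config.horizon_days
    tables = []
    events: list[Patient] | None = None
    rep_max = np.full((config.replications, 3), np.nan)
    n_censored = n_inside = 0
    p4_code = _LEVEL_CODE[AcuityLevel.AL12]
    for r in range(config.replications):
        rng = np.random.default_rng(replication_seed(config.seed, r))
        cols = _simulate_arrays(config, rng)
        n_censored += int(cols["censored"].sum())
        n_inside += int((cols["acuity"] != p4_code).sum())
        table = _table_from_arrays(cols, horizon)
        tables.append(table)
        with np.errstate(invalid="ignore"):
            finite = ~np.isnan(table["ci"]).all(axis=0)
            rep_max[r, finite] = np.nanmax(table["ci"][:, finite], axis=0)
        if keep_events and r == 0:
            events = _records_from_arrays(cols, replication=0)
        if progress and (r + 1) % 50 == 0:
            print(f"  {config.name}: replication {r + 1}/{config.replications}")
    warn_if_censored(n_censored, n_inside)
    daily = aggregate_tables(tables)
    maxima = {l: max_ci(daily, l) for l in TREATED_LEVELS}
    with np.errstate(invalid="ignore"):
        mean_rep_max = {
            l: float(np.nanmean(rep_max[:, j])) for j, l in enumerate(TREATED_LEVELS)
        }
    wait_tot = sum(t["wait_sum"].sum(axis=0) for t in tables)
    n_tot = sum(t["n_treated"].sum(axis=0) for t in tables)
    mean_wait = {
        l: float(wait_tot[j] / n_tot[j]) if n_tot[j] else float("nan")
        for j, l in enumerate(TREATED_LEVELS)
    }
    return ExperimentResult(
        scenario=config,
        daily=daily,
        max_ci=maxima,
        mean_rep_max_ci=mean_rep_max,
        recovery_days=recovery_duration(daily),
        mean_wait=mean_wait,
        replications=config.replications,
        seed=config.seed,
        runtime_seconds=time.perf_counter() - t_start,
        events=events,
    )


def run_sweep(
    ratios: Sequence[float],
    replications: int = 300,
    seed: int = 0,
    breakpoint: float = 1.4,
    progress: bool = False,
    **scenario_kwargs,
) -> tuple[list[ExperimentResult], dict[AcuityLevel, EmpiricalFit]]:
    """Run a sweep over growth ratios and fit the piecewise response.

    Each ratio gets its own scenario (1.0 is the normal state) and a
    seed derived from the master seed; the (P, max CI) points feed the
    two-segment fit for each acuity level.
    """
    ratios = sorted(float(r) for r in ratios)
    if sum(r <= breakpoint for r in ratios) < 2 or sum(r >= breakpoint for r in ratios) < 2:
        raise ValueError(
            f"sweep needs at least two ratios on each side of the breakpoint "
            f"{breakpoint} (the breakpoint itself counts for both); got {ratios}"
        )
    results: list[ExperimentResult] = []
    for i, ratio in enumerate(ratios):
        sub_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31)
        config = build_scenario(
            growth_ratio=ratio, replications=replications, seed=sub_seed, **scenario_kwargs
        )
        if progress:
            print(f"scenario {config.name} (P={ratio:g})")
        results.append(run_experiment(config, progress=progress))
    fits = {}
    for level in TREATED_LEVELS:
        points = [(res.scenario.growth_ratio, res.max_ci[level]) for res in results]
        fits[level] = fit_piecewise(points, level, breakpoint=breakpoint)
    return results, fits


# ---------------------------------------------------------------------------
# Serialization


def _scenario_dict(config: ScenarioConfig) -> dict:
    return {
        "name": config.name,
        "growth_ratio": config.growth_ratio,
        "horizon_days": config.horizon_days,
        "daily_total": list(config.profile.daily_total),
        "phases": list(config.profile.phases),
        "intraday_weights": list(config.profile.intraday_weights)
        if config.profile.intraday_weights
        else None,
        "mixes": {
            "normal": {l.value: v for l, v in config.normal_mix.items()},
            "seismic": {l.value: v for l, v in config.seismic_mix.items()},
        },
        "path_table": {
            l.value: {p.value: v for p, v in row.items()}
            for l, row in config.path_table.items()
        },
        "capacities": {
            k.value: config.stations[k] for k in ServiceKind
        },
        "service_times": {
            k.value: {"family": st.family, "params": list(st.params)}
            for k, st in config.service_times.items()
        },
        "replications": config.replications,
        "seed": config.seed,
    }


def scenario_from_dict(d: Mapping) -> ScenarioConfig:
    """Rebuild a ScenarioConfig from a manifest's config echo.

    Inverse of the manifest serialisation, so any written run can be
    re-derived exactly from its manifest.json.
    """
    from .core import ServiceTime, ServiceTimeConfig, StationSet
    from .scenarios import ArrivalProfile
    from .core import Path as PatientPath

    profile = ArrivalProfile(
        tuple(d["daily_total"]),
        tuple(d["phases"]),
        tuple(d["intraday_weights"]) if d.get("intraday_weights") else None,
    )
    return ScenarioConfig(
        name=d["name"],
        growth_ratio=d["growth_ratio"],
        profile=profile,
        normal_mix={AcuityLevel(k): v for k, v in d["mixes"]["normal"].items()},
        seismic_mix={AcuityLevel(k): v for k, v in d["mixes"]["seismic"].items()},
        path_table={
            AcuityLevel(l): {PatientPath(p): v for p, v in row.items()}
            for l, row in d["path_table"].items()
        },
        stations=StationSet({ServiceKind(k): v for k, v in d["capacities"].items()}),
        service_times=ServiceTimeConfig(
            {
                ServiceKind(k): ServiceTime(v["family"], tuple(v["params"]))
                for k, v in d["service_times"].items()
            }
        ),
        replications=d["replications"],
        seed=d["seed"],
    )


def summary_dict(result: ExperimentResult) -> dict:
    return {
        "scenario": result.scenario.name,
        "growth_ratio": result.scenario.growth_ratio,
        "replications": result.replications,
        "seed": result.seed,
        "horizon_days": result.scenario.horizon_days,
        "max_ci": {l.value: result.max_ci[l] for l in TREATED_LEVELS},
        "mean_replication_max_ci": {
            l.value: result.mean_rep_max_ci[l] for l in TREATED_LEVELS
        },
        "recovery_days": result.recovery_days,
        "mean_wait_minutes": {l.value: result.mean_wait[l] for l in TREATED_LEVELS},
        "runtime_seconds": result.runtime_seconds,
    }


def daily_frame(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for dm in result.daily:
        for l in TREATED_LEVELS:
            rows.append(
                {
                    "day": dm.day,
                    "level": l.value,
                    "ci_mean": dm.ci[l],
                    "ci_sd_across_reps": dm.ci_sd[l],
                    "q": dm.q[l],
                    "n_treated": dm.n_treated[l],
                    "n_arrivals": dm.arrivals,
                }
            )
    return pd.DataFrame(rows)


def fit_dict(fits: Mapping[AcuityLevel, EmpiricalFit]) -> dict:
    return {
        l.value: {
            "breakpoint": f.breakpoint,
            "lower": {"intercept": f.lower.intercept, "slope": f.lower.slope},
            "upper": {"intercept": f.upper.intercept, "slope": f.upper.slope},
        }
        for l, f in fits.items()
    }


def write_outputs(result: ExperimentResult, out_dir) -> list[FilePath]:
    """Write daily_metrics.csv, summary.json and manifest.json.

    When the result carries patient records (``keep_events``), they are
    written to events.csv as well. Returns the written paths.
    """
    out = FilePath(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written = []
    p = out / "daily_metrics.csv"
    daily_frame(result).to_csv(p, index=False)
    written.append(p)
    p = out / "summary.json"
    p.write_text(json.dumps(summary_dict(result), indent=2) + "\n")
    written.append(p)
    p = out / "manifest.json"
    p.write_text(
        json.dumps(
            {"package_version": __version__, "config": _scenario_dict(result.scenario)},
            indent=2,
        )
        + "\n"
    )
    written.append(p)
    if result.events is not None:
        from .core import export_event_log

        p = out / "events.csv"
        export_event_log(result.events, p)
        written.append(p)
    return written
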