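"""Crowdedness Index, Quality and the growth-ratio response equations.

The daily Crowdedness Index of an acuity level is the mean
door-to-doctor time of that level's patients arriving on the day
(whenever they are eventually treated) divided by the level's advised
maximum waiting time T (30/60/120 min for AL3/AL4/AL5):

    CI_AL,j = sum_p (t3_p - t0_p) / (N_AL,j * T_AL)

CI <= 1 means the hospital treats that group within the advised time on
average; CI > 1 flags a timeliness failure. Quality folds CI into a
bounded score, Q = min(1/CI, 1), so a properly functioning department
scores 1 and anything below signals degraded emergency care. The
recovery duration of a surge is the number of days on which any level's
Q sits strictly below 1.

Across surge scenarios, the maximum daily CI responds to the patient
growth ratio P in two regimes separated by a knee at P = 1.4; the
response is summarised by two independently fitted straight lines
sharing the breakpoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import TREATED_LEVELS, AcuityLevel, Patient, waiting_time

__all__ = [
    "DailyMetrics",
    "EmpiricalFit",
    "daily_ci",
    "quality_from_ci",
    "replication_daily_ci",
    "aggregate_daily",
    "aggregate_tables",
    "max_ci",
    "recovery_duration",
    "fit_piecewise",
    "predict_max_ci",
]


@dataclass(frozen=True)
class DailyMetrics:
    """Replication-aggregated metrics for one day (1-based for reporting)."""

    day: int
    ci: Mapping[AcuityLevel, float]
    q: Mapping[AcuityLevel, float]
    ci_sd: Mapping[AcuityLevel, float]
    n_treated: Mapping[AcuityLevel, float]
    arrivals: float


def quality_from_ci(ci: float) -> float:
    """Quality Q = min(1/CI, 1); Q = 1 at CI = 0, NaN propagates."""
    if math.isnan(ci):
        return math.nan
    if ci < 0:
        raise ValueError(f"CI must be non-negative; got {ci}")
    if ci <= 1.0:
        return 1.0
    return 1.0 / ci


def daily_ci(records: Iterable[Patient], level: AcuityLevel, day: int) -> float:
    """CI of one acuity level for patients arriving on ``day`` (0-based).

    Patients are grouped by arrival day even if treated the next day;
    censored (never-treated) patients are excluded. Returns NaN when no
    qualifying patient exists — never a misleading 0.
    """
    if level not in TREATED_LEVELS:
        raise ValueError(f"CI is defined for AL3/AL4/AL5 only; got {level.name}")
    waits = [
        waiting_time(p)
        for p in records
        if p.acuity is level and p.arrival_day == day and p.treated
    ]
    if not waits:
        return math.nan
    return float(np.mean(waits)) / level.advised_max_wait


def replication_daily_ci(
    records: Iterable[Patient], horizon_days: int
) -> dict[str, np.ndarray]:
    """Per-day CI table of a single replication.

    Returns arrays of shape (horizon_days, 3), columns ordered
    AL3/AL4/AL5, plus per-day treated counts, pooled wait sums and
    arrival counts (all acuity levels).
    """
    ci = np.full((horizon_days, 3), np.nan)
    n_treated = np.zeros((horizon_days, 3))
    wait_sum = np.zeros((horizon_days, 3))
    arrivals = np.zeros(horizon_days)
    sums = np.zeros((horizon_days, 3))
    for p in records:
        d = p.arrival_day
        if not 0 <= d < horizon_days:
            continue
        arrivals[d] += 1
        if p.acuity in TREATED_LEVELS and p.treated:
            j = TREATED_LEVELS.index(p.acuity)
            w = waiting_time(p)
            sums[d, j] += w
            wait_sum[d, j] += w
            n_treated[d, j] += 1
    mask = n_treated > 0
    T = np.array([l.advised_max_wait for l in TREATED_LEVELS])
    ci[mask] = (sums[mask] / n_treated[mask]) / np.broadcast_to(T, sums.shape)[mask]
    return {"ci": ci, "n_treated": n_treated, "wait_sum": wait_sum, "arrivals": arrivals}


def aggregate_tables(tables: Sequence[Mapping[str, np.ndarray]]) -> list[DailyMetrics]:
    """Aggregate per-replication CI tables into one daily series.

    Per day and level, CI is the mean across replications of the
    replication-level daily CI (replications with no qualifying patient
    that day are skipped for that cell); Q is computed from the
    aggregated CI.
    """
    if not tables:
        raise ValueError("need at least one replication")
    ci_stack = np.stack([t["ci"] for t in tables])  # (R, H, 3)
    n_stack = np.stack([t["n_treated"] for t in tables])
    arr_stack = np.stack([t["arrivals"] for t in tables])
    with warnings.catch_warnings():
        # all-NaN cells (no qualifying patients in any replication) stay NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_mean = np.nanmean(ci_stack, axis=0)
        ci_sd = (
            np.nanstd(ci_stack, axis=0, ddof=1)
            if len(tables) > 1
            else np.zeros_like(ci_mean)
        )
    out: list[DailyMetrics] = []
    horizon = ci_mean.shape[0]
    for d in range(horizon):
        ci_d = {l: float(ci_mean[d, j]) for j, l in enumerate(TREATED_LEVELS)}
        out.append(
            DailyMetrics(
                day=d + 1,
                ci=ci_d,
                q={l: quality_from_ci(v) for l, v in ci_d.items()},
                ci_sd={l: float(ci_sd[d, j]) for j, l in enumerate(TREATED_LEVELS)},
                n_treated={
                    l: float(n_stack[:, d, j].mean())
                    for j, l in enumerate(TREATED_LEVELS)
                },
                arrivals=float(arr_stack[:, d].mean()),
            )
        )
    return out


def aggregate_daily(
    replications: Sequence[Iterable[Patient]], horizon_days: int
) -> list[DailyMetrics]:
    """Aggregate patient records from one or more replications by day."""
    return aggregate_tables(
        [replication_daily_ci(r, horizon_days) for r in replications]
    )


def max_ci(series: Sequence[DailyMetrics], level: AcuityLevel) -> float:
    """Maximum of a level's aggregated daily CI, ignoring undefined days."""
    if not series:
        raise ValueError("empty daily-metrics series")
    vals = np.asarray([dm.ci[level] for dm in series])
    if np.isnan(vals).all():
        raise ValueError(f"CI for {level.name} is undefined on every day")
    return float(np.nanmax(vals))


def recovery_duration(series: Sequence[DailyMetrics]) -> int:
    """Number of impaired days: days where any level's Q < 1.

    Q is compared at full precision (no rounding); days on which a
    level's Q is undefined are judged on the remaining levels.
    """
    n = 0
    for dm in series:
        qs = [dm.q[l] for l in TREATED_LEVELS if not math.isnan(dm.q[l])]
        if qs and min(qs) < 1.0:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Piecewise response of max CI to the patient growth ratio


@dataclass(frozen=True)
class Segment:
    intercept: float
    slope: float

    def __call__(self, p: float) -> float:
        return self.intercept + self.slope * p


@dataclass(frozen=True)
class EmpiricalFit:
    """Two-segment linear response of max CI to growth ratio P.

    The segments are fitted independently on either side of a fixed
    breakpoint (the knee where the response steepens), with points at
    the breakpoint shared by both segments.
    """

    level: AcuityLevel
    breakpoint: float
    lower: Segment
    upper: Segment


def fit_piecewise(
    points: Sequence[tuple[float, float]],
    level: AcuityLevel,
    breakpoint: float = 1.4,
) -> EmpiricalFit:
    """Least-squares piecewise-linear fit with a fixed breakpoint.

    ``points`` are (growth ratio, max CI) pairs; points with P <= P*
    form the lower segment and points with P >= P* the upper segment
    (P* itself belongs to both). Each side needs at least two points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (growth_ratio, max_ci) pairs")
    lower = pts[pts[:, 0] <= breakpoint]
    upper = pts[pts[:, 0] >= breakpoint]
    if len(lower) < 2 or len(upper) < 2:
        raise ValueError(
            f"need >= 2 points on each side of the breakpoint {breakpoint}; "
            f"got {len(lower)} below and {len(upper)} above (inclusive)"
        )
    segs = []
    for side in (lower, upper):
        slope, intercept = np.polyfit(side[:, 0], side[:, 1], 1)
        segs.append(Segment(float(intercept), float(slope)))
    return EmpiricalFit(level=level, breakpoint=breakpoint, lower=segs[0], upper=segs[1])


def predict_max_ci(fit: EmpiricalFit, p: float) -> float:
    """Evaluate the fitted response at growth ratio ``p`` (>= 1)."""
    if p < 1.0:
        raise ValueError(f"growth ratio must be >= 1; got {p}")
    return fit.lower(p) if p <= fit.breakpoint else fit.upper(p)
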