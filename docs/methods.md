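# Methods

## The model

`edsurge` models one general emergency responsibility hospital as a
feed-forward queueing network of four stations — triage/registration,
consultation/treatment, lab/X-ray, observation — through which simulated
patients move along one of four fixed paths (see the README). Each
station holds a fixed number of *resource units*, each unit being the
aggregate of all labour and devices needed to serve one patient, so a
station's capacity is the number of patients it can serve
simultaneously. Waiting patients queue first-in-first-out with no
priority between acuity levels and no preemption; the identical mean
waits across AL3/AL4/AL5 that the model produces are a direct
consequence of this shared-FIFO assumption. Urgent (AL1/AL2) patients
are diverted to a higher-ranked hospital at generation and consume none
of the modelled hospital's resources; they enter the accounting only
through the growth ratio.

The engine exploits the feed-forward structure: a station's queue-entry
times are exactly the completion times of the previous station, so
solving the stations in topological order (triage, consultation, lab,
observation), each as a FIFO multi-server queue with
earliest-free-server assignment and arrival-order tie-breaking,
reproduces the event schedule of a conventional global event loop while
staying fast enough for hundreds of replications per second. The
equivalence is exercised in the tests against a brute-force event-driven
oracle and, in the exponential/Poisson limit, against the Erlang-C
closed form.

Patient *output* (admission / transfer / discharge dynamics) is not
modelled; a single terminal `depart` event is logged when the last
station of a path completes. Seismic damage to the hospital itself is
out of scope: capacities are constant, and the only driver of
performance change is the patient volume.

## Parameters and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| triage service | Gamma(shape 4.5, scale 0.7) min | mean 3.15 min; the shape/scale reading is adopted (the shape/rate reading, mean 6.4 min, would make triage unstable on busy days) |
| consultation service | Tri(15, 45, 90) min | |
| observation service | Tri(0, 15, 60) min | |
| lab/X-ray service | Tri(30, 75, 120) min | |
| capacities | triage 1, consultation 13, lab 6, observation ∞ | observation is benches in the hall |
| advised max wait `T_AL` | 30 / 60 / 120 min | AL3 / AL4 / AL5; undefined for AL1/AL2 |
| normal mix | AL3 52%, AL4 32%, AL5 6%, AL1/2 10% | lead and recovery days |
| seismic mix | 50 / 30 / 3 / 17% | busy days |
| path table | AL3/AL4: P2 76%, P3 24%; AL5: P1 75%, P2 25%; AL1/2: P4 | |
| baseline volume | 278 AL3–AL5 arrivals/day | |
| replications | 300 | enough that the aggregated daily CI is stable to a few percent |
| horizon | 12 d (P ≤ 1.6), 16 d (P ≤ 2.0), 20 d above | 2 lead + 4 busy + recovery days |

Daily totals are stated in AL3–AL5 (entering) patients; the generated
stream including the diverted AL1/AL2 share has mean `total / (1 −
AL12-share)` for the day's mix, and acuity is drawn from the full mix,
which makes the two accountings consistent by Poisson thinning.

## Arrival process

Arrivals follow a non-homogeneous Poisson process whose intensity is
piecewise-constant per day and integrates to the day's expected count —
the standard choice for patient-arrival simulation, and the one that
lets count variance be absorbed by replication averaging. Within a day
the intensity is uniform by default; a 24-bin hourly weight vector can
be supplied per scenario by users who have a diurnal profile. Daily CI
depends at first order on daily totals, but the within-day shape does
matter at second order: a fluctuating profile congests the single triage
unit more than a uniform one, and the uniform default therefore sits
a few percent below published waiting-time calibrations obtained with
fluctuating hourly rates (≈ 7.9 vs ≈ 9 min on a normal day). We keep
the uniform default rather than invent hourly numbers.

The busy-day totals for growth ratios 1.4 and 1.6 are the published
day-by-day counts ([366, 411, 334, 284] and [449, 509, 371, 298]).
Those two profiles imply effective generated-volume ratios of ≈ 1.36
and ≈ 1.59 under the mix accounting above — the only reading we found
that reconciles the printed 278/day baseline, the printed busy totals
and the nominal ratios. For any other ratio `P` the profile is built by
scaling: the total busy-phase excess in generated-patient units,
`4 × (278/0.90) × (P − 1)`, is laid on top of the normal base in
proportion to the P = 1.6 profile's excess-over-normal day shape, then
converted to AL3–AL5 arrivals with the seismic mix (83%). This
construction delivers the nominal ratio exactly and keeps the
front-loaded two-day peak; because it carries the full nominal excess,
its recovery durations at large `P` run ~2–4 days longer than published
values derived from unpublished arrival curves (see Limitations).

## Metrics

Daily CI per level is the mean door-to-doctor time (`t3 − t0`,
covering triage queue, triage and consultation queue) of that level's
patients **grouped by arrival day** — a patient arriving on day `j` and
treated on day `j+1` counts toward day `j` — divided by `T_AL`. Days
with no qualifying patient yield a missing value, never zero. Patients
whose treatment has not started by the horizon's end are censored and
excluded; horizons are long enough that this is < 0.1% (a warning fires
otherwise).

Replication aggregation takes, per day and level, the mean across
replications of the replication-level daily CI, skipping replications
with an undefined cell; Quality is computed from the aggregated CI.
The alternative (pooling patients across replications before averaging)
differs only at second order; the across-replication mean matches the
intent of replicating to level out outliers, and both the maximum of
the replication-averaged series and the mean of per-replication maxima
are reported in `summary.json`.

The recovery (impaired-day) count is the number of days on which any
level's Quality is strictly below 1, at full precision — a day with
Q = 0.979 is impaired; no epsilon, no rounding. The piecewise max-CI
response is fitted with a fixed knee at `P* = 1.4` (no knee search):
ordinary least squares on the points with `P ≤ P*` and `P ≥ P*`
independently, the knee point belonging to both segments.

## Reproducibility

Each experiment carries one master seed; replication `r` uses the
child stream `SeedSequence([seed, r])`, so replications are independent,
individually re-derivable, and the result is invariant to execution
order. Outputs include a manifest echoing the fully resolved
configuration; `scenario_from_dict` rebuilds the exact scenario from it.
Equal (config, seed) pairs produce byte-identical CSV output.

## What the generator does and does not emulate

The synthetic scenarios reproduce the study conditions: daily volumes,
phase structure (2 lead, 4 busy, recovery), acuity mixes, path
proportions, service-time laws and capacities. They do not emulate
within-day arrival rhythms (unless weights are supplied), day-of-week
effects, correlated arrivals (families, ambulance batches),
level-dependent service times, staff fatigue, or any seismic damage to
capacity. Passing tests therefore demonstrate the queueing consequences
of volume surges under these idealised conditions, not a calibrated
forecast for a specific hospital.

## Numerical choices and degenerate inputs

* Times are float64 minutes from simulation start; a day is a 1440-min
  window and arrival days are 0-based internally, 1-based in reports.
* Queue ties (equal entry times) are broken by patient arrival index,
  making the event schedule deterministic given the random draws.
* A `fixed` service-time family (a point mass) is provided for
  constructing hand-checkable schedules; triangular distributions
  require `min < max`.
* Zero-rate profiles are valid and produce no patients; empty stations
  return empty schedules.
* Proportion vectors must sum to 1 within 1e-9; validation errors name
  the offending key.

## Known limitations

* The uniform within-day default underestimates triage congestion
  relative to fluctuating hourly rates; normal-day CI is ≈ 0.26 rather
  than the ≈ 0.33 published from such rates, with waits ≈ 7.9 vs
  ≈ 9–10 min.
* The scaled profiles for growth ratios beyond 1.6 carry the full
  nominal excess volume; published recovery durations at `P = 2.3`
  (10 days) are shorter than this model's (~14 days), implying the
  original arrival curves carried less total excess or decayed faster
  after the peak. Maximum CIs, which depend mostly on the two peak
  days, agree within tolerance.
* One aggregate resource unit per station ignores staff rosters and
  shift changes; no priority queueing means the model cannot represent
  hospitals that triage-jump higher-acuity patients.
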