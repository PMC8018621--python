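# edsurge

Discrete-event simulation of emergency-department crowdedness in a
*general emergency responsibility hospital* — the lowest rank of
first-aid hospital in Taiwan's emergency care system, tasked with
non-urgent patients (acuity levels AL3–AL5) — under post-earthquake
patient surges.

After a violent earthquake most casualties are minor or moderate
injuries. If severity-based diversion is enforced, these non-urgent
patients flood the general-rank hospitals. `edsurge` quantifies what
that flood does to one such hospital: how long patients wait, how far
the department falls below its timeliness targets, and how many days it
takes to recover — as a function of the *patient growth ratio* `P`, the
ratio of patient visits during the four-day post-quake busy phase to the
normal volume.

The package is for health-system researchers and emergency-preparedness
planners who want a transparent, reproducible queueing model of surge
impact rather than a black-box estimate.

## Model

Patients arrive as a non-homogeneous Poisson process (278 AL3–AL5
visits/day in the normal state; published day-by-day totals for the
`P = 1.4` and `P = 1.6` surges), are assigned an acuity level from the
phase's mix (normal: AL3 52%, AL4 32%, AL5 6%, AL1/2 10%; seismic:
50/30/3/17%) and routed along one of four paths:

1. triage → consultation (AL5)
2. triage → consultation → observation (AL3–AL5)
3. triage → consultation → lab/X-ray → observation (AL3/AL4)
4. diversion of urgent AL1/AL2 patients to a higher-ranked hospital

Stations are FIFO multi-server queues (triage 1 unit, consultation 13,
lab 6, observation unbounded) with random service times (triage
Gamma(shape 4.5, scale 0.7) min; consultation Tri(15, 45, 90);
observation Tri(0, 15, 60); lab Tri(30, 75, 120)).

Performance is measured per day `j` and acuity level by the
**Crowdedness Index**

```
CI_AL,j = mean over patients arriving on day j of (t3 − t0) / T_AL
```

where `t3 − t0` is the door-to-doctor time (arrival to treatment start)
and `T_AL` is the advised maximum wait (30/60/120 min for AL3/AL4/AL5),
and by **Quality** `Q = min(1/CI, 1)`; `Q < 1` flags a hospital that can
no longer treat on time. The maximum daily CI responds to the growth
ratio `P` piecewise linearly with a knee at `P* = 1.4`, fitted as two
independent least-squares segments (`fit_piecewise`).

## Worked example

```python
from edsurge import AcuityLevel, build_scenario, run_experiment

cfg = build_scenario(name="GR1", replications=300, seed=1)   # P = 1.4
res = run_experiment(cfg)
print({l.value: round(res.max_ci[l], 2) for l in res.max_ci})
print("impaired days:", res.recovery_days)
```

prints

```
{'AL3': 4.07, 'AL4': 2.04, 'AL5': 1.03}
impaired days: 3
```

With visits 1.4× the normal volume during the busy phase, AL3 patients
wait on the worst day about four times their 30-minute target (peak mean
wait ≈ 122 min), AL4 about twice their 60-minute target, and AL5
patients just cross theirs — the 4 : 2 : 1 pattern that follows from a
shared FIFO queue and the 30/60/120 targets. Quality drops below 1 on
three days (the last three busy days) and recovers as soon as the surge
ends. The same hospital under normal load (`name="normal"`) shows a
mean door-to-doctor time of ≈ 7.9 minutes and all CIs below 0.3.

Equivalent CLI:

```sh
edsurge run --scenario GR1 --reps 300 --seed 1 --out results/
edsurge sweep --ratios 1.0,1.4,1.6,1.9,2.3 --reps 300 --out results/
edsurge score results/events.csv --horizon-days 12
```

`run` writes `daily_metrics.csv`, `summary.json` and a `manifest.json`
from which the run can be rebuilt exactly; `sweep` additionally fits the
two-segment max-CI response and writes `fit.json`; `score` computes the
metrics for an externally supplied patient event log.

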