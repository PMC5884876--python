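# iltkit

Toolkit for closed-loop, lactate-guided exercise threshold testing on
simulated athletes. It implements:

- **`iltkit.physiology`** — a virtual-subject simulator (blood lactate,
  heart rate, perceived exertion as functions of workload and time) with
  sub-threshold steady states, a steep supra-threshold lactate rise that
  grows with the overshoot above the maximal lactate steady state workload
  (MLSS), an optional 0–7 step accumulation delay, and a 3%-CV analyzer
  noise model; plus seeded cohort generation for running (m/s) and cycling
  (W).
- **`iltkit.criteria`** — pure, stateless detection of the lactate threshold
  in a measured step series via three criteria: TC1 (rise > 0.5 mM directly
  after a workload increment), TC2 (cumulative rise > 0.4 mM within 1–8
  constant-workload steps after an increment) and TC2a (slow creep > 0.1
  mM/step over ≥ 3 consecutive constant-workload steps), usable live or
  retrospectively on recorded logs.
- **`iltkit.controller`** — the adaptive test state machine: HR-guided
  warm-up (target 170 − age bpm), a regression-based first increment, fine
  lactate-guided increments (0.1/0.15 m/s or 7/10 W), start-of-test
  overshoot correction, and MLSS verification by a small workload reduction
  (0.1 m/s / 7 W).
- **`iltkit.studies`** — study harnesses over simulated cohorts: test–retest
  reliability, the effect of increment size on the lactate rise at the
  threshold, and validity against a 10-km constant velocity test (CVT) with
  0.1 m/s escalations.
- **`iltkit.session_io`** — CSV session logs with JSON side-cars (config
  hash included for traceability), cohort CSV round-trips, YAML/JSON
  configuration, and deterministic fixture generation.

## CLI

```bash
# one closed-loop session on a simulated subject
iltk run --modality running --seed 3 --out session.csv

# retrospective threshold detection on a recorded log
iltk detect session.csv --json

# cohort-level studies (per-subject CSV + JSON summary under --out)
iltk study reliability --n 50 --seed 1 --out study_out
iltk study increment   --n 60 --seed 1 --out study_out
iltk study validity    --n 50 --seed 1 --out study_out

# deterministic fixture session logs
iltk fixtures --seed 0 --out-dir fixtures
```

Session logs are RFC-4180 CSV with the columns
`step_index, phase, workload, workload_units, duration_min, lactate_mM,
hr_bpm, rpe, decision, timestamp_min` and a `.json` side-car holding the
threshold decision, the MLSS workload estimate, the outcome, the seed and a
hash of the exact configuration.

Configs are YAML or JSON with `protocol` and/or `cohort` sections, e.g.

```yaml
protocol:
  modality: running
  ta_intercept: 0.05
  measurement: {cv: 0.03}
cohort:
  n: 50
  modality: running
  seed: 7
  ranges:
    mlss_workload: [3.0, 4.8]
```

## Library example

```python
import iltkit as k

cohort = k.make_cohort(50, "running", seed=7)
record = k.run_ilt_test(cohort[0], seed=1)
print(record.threshold.criterion, record.mlss_workload_estimate)

study = k.run_reliability_study(cohort, seed=1)
print(study.summary["pearson_r"], study.summary["mean_abs_difference"])
```

## Determinism

Every stochastic component draws from a named stream derived from one root
seed (`iltkit._rng`), so identical seeds give byte-identical sessions,
cohorts and study outputs, and re-running one session never perturbs
another.
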