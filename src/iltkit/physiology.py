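"""Virtual-subject physiology: lactate, heart-rate and RPE responses to workload.

The model is deliberately the simplest one that reproduces the behaviours an
adaptive lactate-guided step test relies on:

* below the maximal lactate steady state workload (MLSS), blood lactate relaxes
  first-order toward a workload-linear steady state, so every sub-threshold
  workload has a steady state;
* above the MLSS there is no steady state: each completed step adds a strictly
  positive accumulation that grows with the overshoot above the MLSS.  A
  per-subject lag of 0-7 constant-workload steps delays the full accumulation;
  during the lag only a slower "onset" drift is present, which produces the
  delayed-threshold test pattern;
* heart rate relaxes first-order toward a workload-linear target;
* the lactate analyzer is modelled as multiplicative Gaussian noise with a
  configurable coefficient of variation (default 3%).

Workloads are running velocities (m/s) or cycling power (W); all prescribed
workloads are multiples of a modality quantum (0.05 m/s, 1 W).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._rng import stream

__all__ = [
    "RUNNING",
    "CYCLING",
    "workload_quantum",
    "quantize_workload",
    "SubjectProfile",
    "PhysioState",
    "MeasurementModel",
    "initial_state",
    "steady_state_lactate",
    "advance_step",
    "measure_lactate",
    "rpe_response",
    "make_cohort",
    "default_parameter_ranges",
    "REFERENCE_STEP_MINUTES",
]

RUNNING = "running"
CYCLING = "cycling"

#: Smallest representable workload change per modality (m/s, W).
_QUANTA = {RUNNING: 0.05, CYCLING: 1.0}

#: Step duration (minutes) that the supra-threshold accumulation rates are
#: expressed against; shorter/longer steps scale the per-step rise linearly.
REFERENCE_STEP_MINUTES = 4.0


def workload_quantum(modality: str) -> float:
    try:
        return _QUANTA[modality]
    except KeyError:  # pragma: no cover - defensive
        raise ValueError(f"unknown modality: {modality!r}") from None


def quantize_workload(workload: float, modality: str) -> float:
    """Round a workload to the nearest modality quantum."""
    q = workload_quantum(modality)
    return round(round(workload / q) * q, 6)


@dataclass(frozen=True)
class SubjectProfile:
    """Latent physiological parameters of one virtual athlete.

    ``mlss_workload`` is the ground-truth maximal lactate steady state
    workload that protocols try to recover; it is continuous, not snapped to
    the workload quantum.
    """

    id: str
    age: float
    modality: str
    mlss_workload: float
    baseline_lactate: float = 1.0
    sub_threshold_gain: float = 0.45
    supra_threshold_rate: float = 8.0
    supra_onset_rise: float = 0.40
    lactate_time_constant: float = 1.4
    accumulation_lag_steps: int = 0
    hr_rest: float = 60.0
    hr_gain: float = 28.0
    hr_time_constant: float = 0.7
    rpe_at_mlss: float = 5.0

    def __post_init__(self) -> None:
        if self.modality not in _QUANTA:
            raise ValueError(f"unknown modality: {self.modality!r}")
        if not self.mlss_workload > 0:
            raise ValueError("mlss_workload must be > 0")
        if not 0 <= int(self.accumulation_lag_steps) <= 7:
            raise ValueError("accumulation_lag_steps must be in 0..7")
        if not (self.lactate_time_constant > 0 and self.hr_time_constant > 0):
            raise ValueError("time constants must be > 0")
        if not 0.5 <= self.baseline_lactate <= 2.5:
            raise ValueError("baseline_lactate must lie in [0.5, 2.5] mM")
        if self.sub_threshold_gain < 0 or self.supra_threshold_rate < 0:
            raise ValueError("lactate gains must be >= 0")
        if self.supra_onset_rise < 0:
            raise ValueError("supra_onset_rise must be >= 0")
        if self.hr_gain <= 0:
            raise ValueError("hr_gain must be > 0")

    @property
    def implied_lt_lactate(self) -> float:
        """Steady-state lactate at the MLSS workload (the lactate level at
        which this subject's threshold manifests)."""
        return steady_state_lactate(self, self.mlss_workload)


@dataclass(frozen=True)
class PhysioState:
    """Carries true lactate/HR between steps (not directly observable)."""

    true_lactate: float
    hr: float
    steps_at_constant_supra_workload: int = 0
    elapsed_time: float = 0.0
    last_workload: float | None = None

    def __post_init__(self) -> None:
        if self.true_lactate < 0:
            raise ValueError("true_lactate must be >= 0")


@dataclass(frozen=True)
class MeasurementModel:
    """Lactate analyzer model: multiplicative noise with coefficient of
    variation ``cv`` (sd = cv * true value), truncated at zero.

    ``sampling_pause`` is the brief stop for blood sampling; it has no effect
    on the lactate dynamics (negligible against 4-min steps) and only pads the
    logged timestamps, as does ``measurement_delay`` (analysis time).
    """

    cv: float = 0.03
    sampling_pause: float = 0.25
    measurement_delay: float = 1.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def initial_state(subject: SubjectProfile) -> PhysioState:
    """Rested state: lactate at baseline, HR at rest."""
    return PhysioState(true_lactate=subject.baseline_lactate, hr=subject.hr_rest)


def steady_state_lactate(subject: SubjectProfile, workload: float) -> float:
    """Steady-state blood lactate for a sub-threshold workload.

    Linear in workload above a resting reference of zero; above the MLSS the
    same line is only the relaxation target — the accumulation term added by
    :func:`advance_step` prevents an actual steady state there.
    """
    return subject.baseline_lactate + subject.sub_threshold_gain * max(0.0, workload)


def advance_step(
    subject: SubjectProfile,
    state: PhysioState,
    workload: float,
    duration: float,
) -> PhysioState:
    """Advance the subject through ``duration`` minutes at ``workload``.

    Returns the new state.  Lactate relaxes first-order (closed form) toward
    the workload-linear steady state; above the MLSS a per-step accumulation
    is added on top: the slow onset drift during the subject's lag phase, then
    ``supra_onset_rise + supra_threshold_rate * (workload - mlss)`` per
    reference step once the lag has elapsed.  The constant-workload step
    counter resets whenever the prescribed workload changes.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if workload < 0:
        raise ValueError("workload must be >= 0")

    same_workload = state.last_workload is not None and math.isclose(
        workload, state.last_workload, rel_tol=0.0, abs_tol=1e-9
    )
    counter = state.steps_at_constant_supra_workload if same_workload else 0

    decay = math.exp(-duration / subject.lactate_time_constant)
    target = steady_state_lactate(subject, workload)
    lactate = target + (state.true_lactate - target) * decay

    supra = workload > subject.mlss_workload
    if supra:
        # Above the MLSS clearance is saturated: lactate rises toward the
        # production line if below it but never decays within a session.
        lactate = max(lactate, state.true_lactate)
        scale = duration / REFERENCE_STEP_MINUTES
        if counter >= subject.accumulation_lag_steps:
            rise = (
                subject.supra_onset_rise
                + subject.supra_threshold_rate * (workload - subject.mlss_workload)
            ) * scale
        else:
            rise = subject.supra_onset_rise * scale
        lactate += rise
        new_counter = counter + 1
    else:
        new_counter = 0

    hr_target = subject.hr_rest + subject.hr_gain * workload
    hr_decay = math.exp(-duration / subject.hr_time_constant)
    hr = hr_target + (state.hr - hr_target) * hr_decay

    return PhysioState(
        true_lactate=max(0.0, lactate),
        hr=hr,
        steps_at_constant_supra_workload=new_counter,
        elapsed_time=state.elapsed_time + duration,
        last_workload=workload,
    )


def measure_lactate(
    true_lactate: float,
    model: MeasurementModel,
    rng: np.random.Generator,
) -> float:
    """One analyzer reading of ``true_lactate``.

    Multiplicative Gaussian noise with sd = cv * value, truncated at zero.
    With cv = 0 the reading reproduces the true value exactly (and consumes
    no random draws).
    """
    if true_lactate < 0:
        raise ValueError("true_lactate must be >= 0")
    if model.cv == 0:
        return float(true_lactate)
    reading = true_lactate * (1.0 + model.cv * rng.standard_normal())
    return float(max(0.0, reading))


def rpe_response(subject: SubjectProfile, workload: float) -> float:
    """Rating of perceived exertion on the modified 0-10 Borg scale.

    Linear in relative workload, anchored so that the MLSS workload feels
    like ``rpe_at_mlss`` (default 5, the effort sustainable for ~60 min),
    saturating at 10.
    """
    if workload < 0:
        raise ValueError("workload must be >= 0")
    value = subject.rpe_at_mlss * workload / subject.mlss_workload
    return float(min(10.0, max(0.0, value)))


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

#: Band of implied lactate-threshold lactate levels the default cohorts are
#: rejected into.  Narrower than the physiologically observed 1.9-5.0 mM so
#: that the *measured* lactate at the detected threshold (steady level plus
#: the threshold rise itself) also stays inside that observed range.
_IMPLIED_LT_BAND = (2.0, 3.8)

_RUNNING_RANGES: dict[str, tuple[float, float]] = {
    "age": (25.0, 40.0),
    "mlss_workload": (3.0, 4.8),
    "baseline_lactate": (0.8, 1.3),
    "sub_threshold_gain": (0.30, 0.55),
    "supra_threshold_rate": (5.0, 10.0),
    "supra_onset_rise": (0.37, 0.44),
    "lactate_time_constant": (1.0, 1.8),
    "accumulation_lag_steps": (0, 7),
    "hr_rest": (50.0, 70.0),
    "hr_at_mlss": (168.0, 182.0),
    "hr_time_constant": (0.5, 1.0),
    "rpe_at_mlss": (5.0, 5.0),
}

_CYCLING_RANGES: dict[str, tuple[float, float]] = {
    **_RUNNING_RANGES,
    "mlss_workload": (150.0, 350.0),
    "sub_threshold_gain": (0.005, 0.011),
    "supra_threshold_rate": (0.07, 0.14),
}


def default_parameter_ranges(modality: str) -> dict[str, tuple[float, float]]:
    """Per-field sampling intervals for :func:`make_cohort`."""
    if modality == RUNNING:
        return dict(_RUNNING_RANGES)
    if modality == CYCLING:
        return dict(_CYCLING_RANGES)
    raise ValueError(f"unknown modality: {modality!r}")


def _draw(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def make_cohort(
    n: int,
    modality: str = RUNNING,
    parameter_ranges: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Draw ``n`` subjects with parameters uniform over per-field ranges.

    Subjects violating profile invariants (or whose implied threshold lactate
    falls outside the default band) are redrawn; impossible ranges raise a
    ``ValueError``.  Deterministic under ``seed``: each subject has its own
    named random stream, so cohorts of different sizes share their prefix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = default_parameter_ranges(modality)
    if parameter_ranges:
        for key, interval in parameter_ranges.items():
            if key not in ranges:
                raise ValueError(f"unknown cohort parameter: {key!r}")
            lo, hi = float(interval[0]), float(interval[1])
            if hi < lo:
                raise ValueError(f"empty range for {key!r}: {interval}")
            ranges[key] = (lo, hi)

    lt_lo, lt_hi = _IMPLIED_LT_BAND
    subjects: list[SubjectProfile] = []
    for i in range(n):
        rng = stream(seed, "cohort", modality, i)
        for _attempt in range(1000):
            lag_lo, lag_hi = ranges["accumulation_lag_steps"]
            params = dict(
                age=_draw(rng, *ranges["age"]),
                mlss_workload=_draw(rng, *ranges["mlss_workload"]),
                baseline_lactate=_draw(rng, *ranges["baseline_lactate"]),
                sub_threshold_gain=_draw(rng, *ranges["sub_threshold_gain"]),
                supra_threshold_rate=_draw(rng, *ranges["supra_threshold_rate"]),
                supra_onset_rise=_draw(rng, *ranges["supra_onset_rise"]),
                lactate_time_constant=_draw(rng, *ranges["lactate_time_constant"]),
                accumulation_lag_steps=int(rng.integers(int(lag_lo), int(lag_hi) + 1)),
                hr_rest=_draw(rng, *ranges["hr_rest"]),
                hr_time_constant=_draw(rng, *ranges["hr_time_constant"]),
                rpe_at_mlss=_draw(rng, *ranges["rpe_at_mlss"]),
            )
            hr_at_mlss = _draw(rng, *ranges["hr_at_mlss"])
            params["hr_gain"] = (hr_at_mlss - params["hr_rest"]) / params["mlss_workload"]
            try:
                subject = SubjectProfile(
                    id=f"{modality[:3]}-{seed}-{i:04d}", modality=modality, **params
                )
            except ValueError:
                continue
            if lt_lo <= subject.implied_lt_lactate <= lt_hi:
                subjects.append(subject)
                break
        else:
            raise ValueError(
                "could not draw a valid subject from the given parameter ranges"
            )
    return subjects


def with_lag(subject: SubjectProfile, lag: int) -> SubjectProfile:
    """Copy of ``subject`` with a different accumulation lag (test helper)."""
    return replace(subject, accumulation_lag_steps=lag)
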