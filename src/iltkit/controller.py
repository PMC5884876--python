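"""Closed-loop adaptive lactate threshold test controller.

Phases: HR-guided warm-up -> threshold adaptation (one large regression-based
increment) -> fine threshold adaptation (small lactate-guided increments with
threshold classification after every step) -> verification of the maximal
lactate steady state workload by a small reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import criteria
from ._rng import stream
from .criteria import NO_THRESHOLD, Step, ThresholdResult, classify
from .physiology import (
    CYCLING,
    RUNNING,
    MeasurementModel,
    PhysioState,
    SubjectProfile,
    advance_step,
    initial_state,
    measure_lactate,
    quantize_workload,
    rpe_response,
    workload_quantum,
)

__all__ = [
    "ProtocolConfig",
    "SessionRecord",
    "ProtocolError",
    "WarmupResult",
    "FtaDecision",
    "run_warmup",
    "threshold_adaptation",
    "next_workload_fta",
    "handle_overshoot",
    "verify_mlss",
    "run_ilt_test",
]

COMPLETED = "completed"
CORRECTED_OVERSHOOT = "corrected_overshoot"
INVALID = "invalid"


class ProtocolError(RuntimeError):
    """A protocol phase could not be completed (session becomes invalid)."""


@dataclass(frozen=True)
class ProtocolConfig:
    """All tunables of the adaptive test, with treadmill/ergometer defaults.

    ``fta_table`` maps the last inter-step lactate delta to the next workload
    increment: the first band is entered with ``delta < bound`` (strict), the
    following bands with ``delta <= bound``; any delta beyond the last bound
    means *hold* (a threshold decision is pending).
    """

    modality: str = RUNNING
    step_duration: float = 4.0
    warmup_hr_offset: float = 170.0
    warmup_tick: float = 0.5
    warmup_settle_band: float = 0.5
    warmup_settle_minutes: float = 1.0
    warmup_timeout: float = 40.0
    warmup_kp: float = 0.01
    warmup_tail_minutes: float = 3.0
    ta_slope: float = 0.30
    ta_intercept: float = 0.05
    fta_table: tuple[tuple[float, float], ...] = ((0.2, 0.15), (0.4, 0.10))
    increments: tuple[float, ...] = (0.1, 0.15, 0.3)
    verification_reduction: float = 0.1
    verification_tolerance: float = 0.2
    max_verification_reductions: int = 2
    overshoot_cutoff: float = 1.0
    overshoot_abs_lactate: float = 5.0
    overshoot_reduction: float = 0.2
    max_steps: int = 20
    tc1_threshold: float = 0.5
    tc2_threshold: float = 0.4
    tc2_window: int = 8
    rise_epsilon: float = 0.1
    hold_cap: int = 8
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    exhaustion_extension: bool = False

    def __post_init__(self) -> None:
        if self.max_steps < 6:
            raise ValueError("max_steps must be >= 6")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be > 0")
        if not self.fta_table:
            raise ValueError("fta_table must have at least one band")

    @property
    def quantum(self) -> float:
        return workload_quantum(self.modality)

    @classmethod
    def default(cls, modality: str = RUNNING, **overrides) -> "ProtocolConfig":
        if modality == RUNNING:
            return cls(modality=RUNNING, **overrides)
        if modality == CYCLING:
            defaults = dict(
                modality=CYCLING,
                warmup_kp=0.6,
                ta_slope=0.30,
                ta_intercept=5.0,
                fta_table=((0.2, 10.0), (0.4, 7.0)),
                increments=(7.0, 10.0, 15.0),
                verification_reduction=7.0,
                overshoot_reduction=14.0,
            )
            defaults.update(overrides)
            return cls(**defaults)
        raise ValueError(f"unknown modality: {modality!r}")


@dataclass(frozen=True)
class SessionRecord:
    """One full test session: every step, the threshold decision, the MLSS
    workload estimate and the overall outcome."""

    subject_id: str
    config: ProtocolConfig
    steps: tuple[Step, ...]
    threshold: ThresholdResult
    mlss_workload_estimate: float | None
    outcome: str
    seed: int
    invalid_reason: str | None = None

    @property
    def completed(self) -> bool:
        return self.outcome in (COMPLETED, CORRECTED_OVERSHOOT)


class WarmupResult(NamedTuple):
    workload: float
    lactate: float
    state: PhysioState
    duration: float


class FtaDecision(NamedTuple):
    action: str  # "increase" | "hold"
    increment: float
    delta: float


def run_warmup(
    subject: SubjectProfile,
    config: ProtocolConfig,
    rng: np.random.Generator,
    state: PhysioState | None = None,
) -> WarmupResult:
    """HR-guided warm-up at a target of ``warmup_hr_offset - age`` bpm.

    A proportional (integrating) feedback loop nudges the workload every
    control tick until the simulated HR stays within the settle band of the
    target for one full minute; the workload is then quantized and held for a
    short tail so lactate approaches its steady state before the baseline
    sample is taken.
    """
    target = config.warmup_hr_offset - subject.age
    if target <= subject.hr_rest:
        raise ProtocolError(
            f"warm-up HR target {target:.0f} bpm not reachable "
            f"(resting HR {subject.hr_rest:.0f} bpm)"
        )
    if state is None:
        state = initial_state(subject)
    start_time = state.elapsed_time
    workload = 0.0
    settled_for = 0.0
    while state.elapsed_time - start_time < config.warmup_timeout:
        state = advance_step(subject, state, workload, config.warmup_tick)
        error = target - state.hr
        if abs(error) <= config.warmup_settle_band:
            settled_for += config.warmup_tick
            if settled_for >= config.warmup_settle_minutes:
                break
        else:
            settled_for = 0.0
        workload = max(0.0, workload + config.warmup_kp * error)
    else:
        raise ProtocolError("warm-up HR target not reached before timeout")

    settled = quantize_workload(workload, config.modality)
    if config.warmup_tail_minutes > 0:
        state = advance_step(subject, state, settled, config.warmup_tail_minutes)
    lactate = measure_lactate(state.true_lactate, config.measurement, rng)
    return WarmupResult(settled, lactate, state, state.elapsed_time - start_time)


def threshold_adaptation(
    warmup_workload: float,
    warmup_lactate: float,
    config: ProtocolConfig,
) -> float:
    """First post-warm-up workload from the configured regression mapping.

    The increment is floored at one workload quantum, so the first workload
    always exceeds the warm-up workload.
    """
    increment = max(
        config.quantum, config.ta_slope * warmup_workload + config.ta_intercept
    )
    return quantize_workload(warmup_workload + increment, config.modality)


def next_workload_fta(history: Sequence[Step], config: ProtocolConfig) -> FtaDecision:
    """Workload decision from the last inter-step lactate delta.

    Small deltas mean the threshold is still far: step up by the larger
    increment.  Moderate deltas shrink the increment.  A large delta at this
    point means a threshold decision is pending: hold the workload.
    """
    if len(history) < 1:
        raise ValueError("need at least one completed step")
    if len(history) == 1:
        delta = 0.0
    else:
        delta = round(
            history[-1].measured_lactate - history[-2].measured_lactate, 2
        )
    first_bound, first_inc = config.fta_table[0]
    if delta < first_bound:
        return FtaDecision("increase", first_inc, delta)
    for bound, inc in config.fta_table[1:]:
        if delta <= bound:
            return FtaDecision("increase", inc, delta)
    return FtaDecision("hold", 0.0, delta)


def _tc2_window_open(history: Sequence[Step], window: int) -> bool:
    """True while a completed step could still fire TC2: the most recent
    workload change was an increase at most ``window - 1`` steps ago."""
    last_change = None
    increase = False
    for t in range(1, len(history)):
        if history[t].workload != history[t - 1].workload:
            last_change = t
            increase = history[t].workload > history[t - 1].workload
    if last_change is None or not increase:
        return False
    return (len(history) - 1 - last_change) < window - 1


def handle_overshoot(history: Sequence[Step], config: ProtocolConfig) -> float:
    """Corrected workload after a too-high start (reduction below the last
    prescribed workload, floored at one quantum)."""
    corrected = history[-1].workload - config.overshoot_reduction
    return max(config.quantum, quantize_workload(corrected, config.modality))


def _run_step(
    subject: SubjectProfile,
    state: PhysioState,
    workload: float,
    config: ProtocolConfig,
    rng: np.random.Generator,
    index: int,
    phase: str,
    duration: float | None = None,
) -> tuple[Step, PhysioState]:
    duration = config.step_duration if duration is None else duration
    state = advance_step(subject, state, workload, duration)
    lactate = measure_lactate(state.true_lactate, config.measurement, rng)
    timestamp = (
        state.elapsed_time
        + config.measurement.sampling_pause
        + config.measurement.measurement_delay
    )
    step = Step(
        index=index,
        workload=workload,
        duration=duration,
        measured_lactate=round(lactate, 2),
        hr=round(state.hr, 1),
        rpe=round(rpe_response(subject, workload), 1),
        phase=phase,
        timestamp=round(timestamp, 2),
    )
    return step, state


def _with_decision(step: Step, decision: str) -> Step:
    return replace(step, decision=decision)


def verify_mlss(
    subject: SubjectProfile,
    state: PhysioState,
    steps: list[Step],
    threshold: ThresholdResult,
    config: ProtocolConfig,
    rng: np.random.Generator,
    seed: int,
    overshoot_corrected: bool = False,
) -> SessionRecord:
    """Verify the MLSS workload by stepping the workload down from the
    detected threshold workload.

    Each reduction runs one step; if the lactate change over that step is at
    most ``verification_tolerance`` the session completes with the reduced
    workload as the MLSS estimate.  After ``max_verification_reductions``
    failed reductions the session is invalid.
    """
    if not threshold.fired:
        raise ValueError("verification requires a fired threshold criterion")
    outcome = INVALID
    estimate: float | None = None
    reason: str | None = "verification failed"
    workload = threshold.lt_workload
    for attempt in range(1, config.max_verification_reductions + 1):
        workload = quantize_workload(
            workload - config.verification_reduction, config.modality
        )
        if workload <= 0:
            reason = "verification workload fell to zero"
            break
        step, state = _run_step(
            subject, state, workload, config, rng,
            index=steps[-1].index + 1, phase="verification",
        )
        delta = round(step.measured_lactate - steps[-1].measured_lactate, 2)
        ok = delta <= config.verification_tolerance
        step = _with_decision(
            step,
            f"verify:pass(d={delta:+.2f})" if ok else f"verify:fail(d={delta:+.2f})",
        )
        steps.append(step)
        if ok:
            estimate = workload
            outcome = CORRECTED_OVERSHOOT if overshoot_corrected else COMPLETED
            reason = None
            break

    if outcome != INVALID and config.exhaustion_extension:
        # Optional post-verification re-increment (does not affect the estimate).
        ext = quantize_workload(
            threshold.lt_workload + config.fta_table[0][1], config.modality
        )
        for _ in range(2):
            step, state = _run_step(
                subject, state, ext, config, rng,
                index=steps[-1].index + 1, phase="post",
            )
            steps.append(_with_decision(step, "exhaustion_extension"))

    return SessionRecord(
        subject_id=subject.id,
        config=config,
        steps=tuple(steps),
        threshold=threshold,
        mlss_workload_estimate=estimate,
        outcome=outcome,
        seed=seed,
        invalid_reason=reason,
    )


def _invalid(subject, config, steps, seed, reason) -> SessionRecord:
    return SessionRecord(
        subject_id=subject.id,
        config=config,
        steps=tuple(steps),
        threshold=NO_THRESHOLD,
        mlss_workload_estimate=None,
        outcome=INVALID,
        seed=seed,
        invalid_reason=reason,
    )


def run_ilt_test(
    subject: SubjectProfile,
    config: ProtocolConfig | None = None,
    seed: int = 0,
) -> SessionRecord:
    """Execute one full adaptive test session on a simulated subject.

    Deterministic under ``(subject, config, seed)``.  Classification runs
    after every fine-adaptation step over the series starting at the
    threshold-adaptation step, so the large initial increment itself can
    never fire a criterion.
    """
    if config is None:
        config = ProtocolConfig.default(subject.modality)
    if config.modality != subject.modality:
        raise ValueError("config modality does not match subject modality")
    rng = stream(seed, "session", subject.id)

    steps: list[Step] = []
    try:
        warm = run_warmup(subject, config, rng)
    except ProtocolError as err:
        return _invalid(subject, config, steps, seed, str(err))
    state = warm.state
    steps.append(
        Step(
            index=0,
            workload=warm.workload,
            duration=round(warm.duration, 2),
            measured_lactate=round(warm.lactate, 2),
            hr=round(state.hr, 1),
            rpe=round(rpe_response(subject, warm.workload), 1),
            phase="warmup",
            timestamp=round(state.elapsed_time, 2),
        )
    )

    workload = threshold_adaptation(warm.workload, warm.lactate, config)
    steps[-1] = _with_decision(steps[-1], f"TA:{workload - warm.workload:+.2f}")

    ta_position = len(steps)  # classification window starts at the TA step
    step, state = _run_step(
        subject, state, workload, config, rng, index=1, phase="adaptation"
    )
    steps.append(step)

    overshoot_corrected = False
    overshoot_watch = True  # the start-of-test correction rule is armed
    hold_run = 0
    protocol_steps = 1  # steps after warm-up

    while True:
        result = classify(
            steps[ta_position:],
            tc1_threshold=config.tc1_threshold,
            tc2_threshold=config.tc2_threshold,
            tc2_window=config.tc2_window,
            rise_epsilon=config.rise_epsilon,
        )
        if result.fired:
            steps[-1] = _with_decision(
                steps[-1],
                f"{result.criterion}:reduce{-config.verification_reduction:+g}",
            )
            return verify_mlss(
                subject, state, steps, result, config, rng, seed,
                overshoot_corrected=overshoot_corrected,
            )

        last = steps[-1]
        prev = steps[-2]
        delta = round(last.measured_lactate - prev.measured_lactate, 2)
        if overshoot_watch and (
            delta > config.overshoot_cutoff
            or last.measured_lactate > config.overshoot_abs_lactate
        ):
            if overshoot_corrected:
                steps[-1] = _with_decision(last, "overshoot:abort")
                return _invalid(
                    subject, config, steps, seed, "second consecutive overshoot"
                )
            workload = handle_overshoot(steps, config)
            overshoot_corrected = True
            steps[-1] = _with_decision(last, f"overshoot:correct->{workload:g}")
        else:
            overshoot_watch = False  # rule only covers the start of the test
            decision = next_workload_fta(steps[ta_position:], config)
            window_open = _tc2_window_open(steps[ta_position:], config.tc2_window)
            if decision.action == "hold" and window_open and hold_run < config.hold_cap:
                hold_run += 1
                steps[-1] = _with_decision(last, "hold")
            elif decision.action == "hold":
                # Rising lactate but no window a criterion could fire in:
                # probe upward with the small increment to open one.
                hold_run = 0
                probe = config.fta_table[-1][1]
                workload = quantize_workload(last.workload + probe, config.modality)
                steps[-1] = _with_decision(last, f"probe:{probe:+g}")
            else:
                hold_run = 0
                workload = quantize_workload(
                    last.workload + decision.increment, config.modality
                )
                steps[-1] = _with_decision(last, f"FTA:{decision.increment:+g}")

        if protocol_steps >= config.max_steps:
            return _invalid(
                subject, config, steps, seed, "max_steps reached without a criterion"
            )
        step, state = _run_step(
            subject, state, workload, config, rng,
            index=steps[-1].index + 1, phase="fine_adaptation",
        )
        steps.append(step)
        protocol_steps += 1
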