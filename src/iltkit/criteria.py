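"""Pure, stateless classification of measured lactate step series.

Three criteria mark the lactate threshold:

* **TC1** — lactate rises more than 0.5 mM (strict) in the step directly
  after a workload increment.
* **TC2** — lactate rises more than 0.4 mM (strict, cumulative against the
  last step before the increment) one to eight steps after the increment,
  with the workload held constant since.
* **TC2a** — the rise never reaches those criteria, but lactate creeps up by
  more than ``rise_epsilon`` per step over at least three consecutive
  constant-workload steps while the cumulative rise stays at or below 0.5 mM.

Deltas are rounded to 0.01 mM before comparison so that series written to
and read back from logs (0.01 mM precision) classify identically.  TC1 and
TC2 are resolved by earliest firing step (TC1 wins a same-step tie); TC2a is
a fallback that only applies when neither fires anywhere in the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TC1",
    "TC2",
    "TC2A",
    "NONE",
    "Step",
    "ThresholdResult",
    "detect_tc1",
    "detect_tc2",
    "detect_tc2a",
    "classify",
    "classification_window",
]

TC1 = "TC1"
TC2 = "TC2"
TC2A = "TC2a"
NONE = "none"

PHASES = ("warmup", "adaptation", "fine_adaptation", "verification", "post")


@dataclass(frozen=True)
class Step:
    """One completed protocol stage with its end-of-step measurements."""

    index: int
    workload: float
    duration: float
    measured_lactate: float
    hr: float | None = None
    rpe: float | None = None
    phase: str = "fine_adaptation"
    decision: str = ""
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("step index must be >= 0")
        if self.measured_lactate < 0:
            raise ValueError("measured_lactate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase: {self.phase!r}")


@dataclass(frozen=True)
class ThresholdResult:
    """Which criterion fired, where, and the workload/lactate at the LT.

    ``reference_step`` is the position (within the classified series) of the
    last step completed before the triggering workload increment — the
    baseline the delta is measured against.  Positions are list offsets, not
    the ``Step.index`` labels.
    """

    criterion: str = NONE
    trigger_step: int | None = None
    reference_step: int | None = None
    delta_lactate: float | None = None
    lt_workload: float | None = None
    lt_lactate: float | None = None

    @property
    def fired(self) -> bool:
        return self.criterion != NONE


NO_THRESHOLD = ThresholdResult()


def _round2(value: float) -> float:
    return round(value, 2)


def _validate(steps: Sequence[Step]) -> None:
    if len(steps) == 0:
        raise ValueError("empty step series")
    for prev, cur in zip(steps, steps[1:]):
        if cur.index <= prev.index:
            raise ValueError("step indices must be strictly increasing")


def _result(steps: Sequence[Step], criterion: str, trigger: int, ref: int) -> ThresholdResult:
    return ThresholdResult(
        criterion=criterion,
        trigger_step=trigger,
        reference_step=ref,
        delta_lactate=_round2(steps[trigger].measured_lactate - steps[ref].measured_lactate),
        lt_workload=steps[trigger].workload,
        lt_lactate=steps[trigger].measured_lactate,
    )


def _scan_tc1_tc2(
    steps: Sequence[Step],
    tc1_threshold: float,
    tc2_threshold: float,
    tc2_window: int,
    enabled: Iterable[str] = (TC1, TC2),
) -> ThresholdResult:
    """Forward scan for the earliest TC1/TC2 firing.

    The reference resets at every workload change: an increase opens a new
    detection window anchored at the preceding step, a decrease closes it.
    """
    enabled = set(enabled)
    ref: int | None = None
    for t in range(1, len(steps)):
        if steps[t].workload > steps[t - 1].workload:
            ref = t - 1
        elif steps[t].workload < steps[t - 1].workload:
            ref = None
        if ref is None:
            continue
        k = t - ref  # constant-workload steps since the increment
        delta = _round2(steps[t].measured_lactate - steps[ref].measured_lactate)
        if k == 1 and TC1 in enabled and delta > tc1_threshold:
            return _result(steps, TC1, t, ref)
        if k <= tc2_window and TC2 in enabled and delta > tc2_threshold:
            if not (k == 1 and delta > tc1_threshold):  # TC1 takes the same-step tie
                return _result(steps, TC2, t, ref)
    return NO_THRESHOLD


def _scan_tc2a(
    steps: Sequence[Step],
    rise_epsilon: float,
    cumulative_cap: float,
) -> ThresholdResult:
    """Earliest window of 3 consecutive slow constant-workload rises.

    Each of the three steps must rise by more than ``rise_epsilon`` at
    unchanged workload, and the cumulative rise over the window must stay at
    or below ``cumulative_cap``.
    """
    run_len = 0
    for t in range(1, len(steps)):
        constant = steps[t].workload == steps[t - 1].workload
        rise = _round2(steps[t].measured_lactate - steps[t - 1].measured_lactate)
        run_len = run_len + 1 if (constant and rise > rise_epsilon) else 0
        if run_len >= 3:
            cum = _round2(
                steps[t].measured_lactate - steps[t - 3].measured_lactate
            )
            if cum <= cumulative_cap:
                return _result(steps, TC2A, t, t - 3)
    return NO_THRESHOLD


def detect_tc1(steps: Sequence[Step], threshold: float = 0.5) -> ThresholdResult:
    """Earliest TC1 firing (rise > ``threshold`` directly after an increment)."""
    _validate(steps)
    return _scan_tc1_tc2(steps, threshold, float("inf"), 8, enabled=(TC1,))


def detect_tc2(
    steps: Sequence[Step],
    threshold: float = 0.4,
    window: int = 8,
    tc1_threshold: float = 0.5,
) -> ThresholdResult:
    """Earliest TC2 firing (cumulative rise > ``threshold`` within 1..window
    constant-workload steps after an increment, TC1-sized same-step rises
    excluded)."""
    _validate(steps)
    return _scan_tc1_tc2(steps, tc1_threshold, threshold, window, enabled=(TC2,))


def detect_tc2a(
    steps: Sequence[Step],
    rise_epsilon: float = 0.1,
    cumulative_cap: float = 0.5,
) -> ThresholdResult:
    """Earliest TC2a firing (slow creep over >= 3 consecutive constant steps)."""
    _validate(steps)
    return _scan_tc2a(steps, rise_epsilon, cumulative_cap)


def classification_window(steps: Sequence[Step]) -> list[Step]:
    """Steps a retrospective detection should run over.

    Drops leading warm-up steps (when phase annotations are present) so the
    large warm-up -> threshold-adaptation transition is not mistaken for a
    fine workload increment — the same scoping the live controller applies.
    """
    out = list(steps)
    while out and out[0].phase == "warmup":
        out.pop(0)
    return out if out else list(steps)


def classify(
    steps: Sequence[Step],
    tc1_threshold: float = 0.5,
    tc2_threshold: float = 0.4,
    tc2_window: int = 8,
    rise_epsilon: float = 0.1,
) -> ThresholdResult:
    """Apply TC1/TC2 (earliest firing step; TC1 wins same-step ties), then
    TC2a as a whole-series fallback.  Pure and idempotent."""
    _validate(steps)
    result = _scan_tc1_tc2(steps, tc1_threshold, tc2_threshold, tc2_window)
    if result.fired:
        return result
    return _scan_tc2a(steps, rise_epsilon, cumulative_cap=tc1_threshold)
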