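"""Readers/writers for session logs, cohort files and protocol configs.

Session logs are RFC-4180 CSV (UTF-8, '.' decimal) with a JSON side-car
carrying the threshold decision, MLSS estimate, outcome, seed and a hash of
the exact configuration, so every result is traceable to its parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ._rng import stream, substream_seed
from .controller import (
    COMPLETED,
    CORRECTED_OVERSHOOT,
    INVALID,
    ProtocolConfig,
    SessionRecord,
    run_ilt_test,
)
from .criteria import NO_THRESHOLD, Step, ThresholdResult
from .physiology import (
    MeasurementModel,
    SubjectProfile,
    make_cohort,
    quantize_workload,
)

__all__ = [
    "SESSION_COLUMNS",
    "write_session",
    "read_session",
    "write_sessions",
    "cohort_to_csv",
    "cohort_from_csv",
    "load_config",
    "load_protocol_config",
    "load_cohort_spec",
    "config_hash",
    "config_to_dict",
    "generate_fixtures",
]

SESSION_COLUMNS = [
    "step_index",
    "phase",
    "workload",
    "workload_units",
    "duration_min",
    "lactate_mM",
    "hr_bpm",
    "rpe",
    "decision",
    "timestamp_min",
]

_UNITS = {"running": "m/s", "cycling": "W"}
_MODALITY_BY_UNIT = {unit: modality for modality, unit in _UNITS.items()}


# --------------------------------------------------------------------------
# Config serialisation
# --------------------------------------------------------------------------

def config_to_dict(config: ProtocolConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["fta_table"] = [list(band) for band in config.fta_table]
    raw["increments"] = list(config.increments)
    return raw


def config_hash(config: ProtocolConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _config_from_dict(raw: dict) -> ProtocolConfig:
    raw = dict(raw)
    measurement = raw.pop("measurement", None)
    if isinstance(measurement, dict):
        raw["measurement"] = MeasurementModel(**measurement)
    if "fta_table" in raw:
        raw["fta_table"] = tuple(tuple(band) for band in raw["fta_table"])
    if "increments" in raw:
        raw["increments"] = tuple(raw["increments"])
    modality = raw.pop("modality", "running")
    return ProtocolConfig.default(modality, **raw)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_protocol_config(path: str | Path) -> ProtocolConfig:
    """Build a :class:`ProtocolConfig` from the ``protocol`` section (or the
    whole document) of a YAML/JSON config file."""
    raw = load_config(path)
    section = raw.get("protocol", raw) if isinstance(raw, dict) else raw
    return _config_from_dict(section or {})


def load_cohort_spec(path: str | Path) -> list[SubjectProfile]:
    """Build a cohort from the ``cohort`` section of a config file.

    Expected keys: ``n``, ``modality``, ``seed`` and optional ``ranges``
    (field name -> [low, high])."""
    raw = load_config(path)
    section = raw.get("cohort", raw)
    if not isinstance(section, dict) or "n" not in section:
        raise ValueError(f"no cohort specification found in {path}")
    return make_cohort(
        n=int(section["n"]),
        modality=section.get("modality", "running"),
        parameter_ranges=section.get("ranges"),
        seed=int(section.get("seed", 0)),
    )


# --------------------------------------------------------------------------
# Session logs
# --------------------------------------------------------------------------

def _session_frame(record: SessionRecord) -> pd.DataFrame:
    unit = _UNITS[record.config.modality]
    rows = [
        {
            "step_index": step.index,
            "phase": step.phase,
            "workload": round(step.workload, 6),
            "workload_units": unit,
            "duration_min": round(step.duration, 2),
            "lactate_mM": round(step.measured_lactate, 2),
            "hr_bpm": "" if step.hr is None else round(step.hr, 1),
            "rpe": "" if step.rpe is None else round(step.rpe, 1),
            "decision": step.decision,
            "timestamp_min": "" if step.timestamp is None else round(step.timestamp, 2),
        }
        for step in record.steps
    ]
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session(record: SessionRecord, path: str | Path) -> Path:
    """Write one session as CSV plus a ``.json`` summary side-car."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _session_frame(record).to_csv(path, index=False)
    summary = {
        "subject_id": record.subject_id,
        "outcome": record.outcome,
        "mlss_workload_estimate": record.mlss_workload_estimate,
        "threshold": dataclasses.asdict(record.threshold),
        "seed": record.seed,
        "invalid_reason": record.invalid_reason,
        "config_hash": config_hash(record.config),
        "config": config_to_dict(record.config),
    }
    path.with_suffix(".json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    return path


class SessionFormatError(ValueError):
    """Malformed session log (reported with 1-based file line numbers)."""


def _parse_optional(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_session(path: str | Path) -> SessionRecord:
    """Read a session log (and its side-car, when present) back into a
    :class:`SessionRecord`.

    Externally recorded logs without a side-car are accepted: they come back
    with an empty threshold result and outcome ``invalid`` so the detector
    can be run on their steps retrospectively.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"decision": str}, keep_default_na=False,
                        na_values=[""])
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")
    units = set(frame["workload_units"].dropna().unique())
    if len(units) > 1:
        raise SessionFormatError(f"{path}: mixed workload units {sorted(units)}")
    unit = units.pop() if units else "m/s"
    if unit not in _MODALITY_BY_UNIT:
        raise SessionFormatError(f"{path}: unknown workload unit {unit!r}")
    modality = _MODALITY_BY_UNIT[unit]

    steps = []
    for pos, row in frame.iterrows():
        line = pos + 2  # header is line 1
        try:
            lactate = float(row["lactate_mM"])
            if lactate < 0:
                raise ValueError(f"negative lactate {lactate}")
            decision = row["decision"]
            steps.append(
                Step(
                    index=int(row["step_index"]),
                    workload=float(row["workload"]),
                    duration=float(row["duration_min"]),
                    measured_lactate=lactate,
                    hr=_parse_optional(row["hr_bpm"]),
                    rpe=_parse_optional(row["rpe"]),
                    phase=str(row["phase"]),
                    decision="" if decision is None else str(decision),
                    timestamp=_parse_optional(row["timestamp_min"]),
                )
            )
        except (TypeError, ValueError) as err:
            raise SessionFormatError(f"{path}: line {line}: {err}") from err

    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        summary = json.loads(sidecar.read_text(encoding="utf-8"))
        config = _config_from_dict(summary.get("config", {"modality": modality}))
        threshold = ThresholdResult(**summary.get("threshold", {}))
        return SessionRecord(
            subject_id=summary.get("subject_id", path.stem),
            config=config,
            steps=tuple(steps),
            threshold=threshold,
            mlss_workload_estimate=summary.get("mlss_workload_estimate"),
            outcome=summary.get("outcome", INVALID),
            seed=summary.get("seed", 0),
            invalid_reason=summary.get("invalid_reason"),
        )
    return SessionRecord(
        subject_id=path.stem,
        config=ProtocolConfig.default(modality),
        steps=tuple(steps),
        threshold=NO_THRESHOLD,
        mlss_workload_estimate=None,
        outcome=INVALID,
        seed=0,
        invalid_reason="external log: no session summary",
    )


def write_sessions(records: Sequence[SessionRecord], directory: str | Path) -> Path:
    """Write a batch of sessions plus one summary index CSV; returns the
    index path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, record in enumerate(records):
        name = f"session_{i:04d}_{record.subject_id}.csv"
        write_session(record, directory / name)
        rows.append(
            {
                "file": name,
                "subject_id": record.subject_id,
                "outcome": record.outcome,
                "criterion": record.threshold.criterion,
                "mlss_workload_estimate": record.mlss_workload_estimate,
                "seed": record.seed,
            }
        )
    index = directory / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


# --------------------------------------------------------------------------
# Cohort files
# --------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "id", "age", "modality", "mlss_workload", "baseline_lactate",
    "sub_threshold_gain", "supra_threshold_rate", "supra_onset_rise",
    "lactate_time_constant", "accumulation_lag_steps", "hr_rest", "hr_gain",
    "hr_time_constant", "rpe_at_mlss",
]


def cohort_to_csv(cohort: Sequence[SubjectProfile], path: str | Path) -> Path:
    """One subject per row; workload columns are in modality units
    (m/s for running, W for cycling)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [{col: getattr(s, col) for col in _COHORT_COLUMNS} for s in cohort]
    )
    # %.17g keeps the latent parameters exact through a write/read cycle
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def cohort_from_csv(path: str | Path) -> list[SubjectProfile]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing cohort columns {missing}")
    subjects = []
    for _, row in frame.iterrows():
        kwargs = {col: row[col] for col in _COHORT_COLUMNS}
        kwargs["id"] = str(kwargs["id"])
        kwargs["modality"] = str(kwargs["modality"])
        kwargs["accumulation_lag_steps"] = int(kwargs["accumulation_lag_steps"])
        subjects.append(SubjectProfile(**kwargs))
    return subjects


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

def _constructed_record(
    subject_id: str,
    config: ProtocolConfig,
    steps: Sequence[Step],
    threshold: ThresholdResult,
    estimate: float | None,
    outcome: str,
    seed: int,
    reason: str | None = None,
) -> SessionRecord:
    return SessionRecord(
        subject_id=subject_id,
        config=config,
        steps=tuple(steps),
        threshold=threshold,
        mlss_workload_estimate=estimate,
        outcome=outcome,
        seed=seed,
        invalid_reason=reason,
    )


def _mk_steps(workloads, lactates, phase="fine_adaptation", duration=4.0):
    return [
        Step(index=i, workload=w, duration=duration, measured_lactate=l, phase=phase)
        for i, (w, l) in enumerate(zip(workloads, lactates))
    ]


def generate_fixtures(seed: int = 0, directory: str | Path = "fixtures") -> dict[str, Path]:
    """Write a deterministic set of representative session logs.

    ``tc1``/``overshoot``/``invalid`` are produced by running the closed-loop
    controller on purpose-built subjects; ``tc2_delayed`` (threshold only
    appearing after 8 constant-workload steps) and ``tc2a`` (slow creep) are
    constructed logs with the shapes the live criteria must fire on.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # Noiseless analyzer: the fixture shapes are exact and seed-independent.
    config = ProtocolConfig.default("running", measurement=MeasurementModel(cv=0.0))
    paths: dict[str, Path] = {}

    def _base_subject(sid: str, **overrides) -> SubjectProfile:
        params = dict(
            id=sid, age=30.0, modality="running", mlss_workload=4.0,
            baseline_lactate=1.0, sub_threshold_gain=0.45,
            supra_threshold_rate=7.0, supra_onset_rise=0.4,
            lactate_time_constant=1.2, accumulation_lag_steps=0,
            hr_rest=60.0, hr_gain=28.0, hr_time_constant=0.7,
        )
        params.update(overrides)
        return SubjectProfile(**params)

    # TC1: immediate steep rise at the threshold, closed loop.
    tc1_record = run_ilt_test(
        _base_subject("fixture-tc1"), config, seed=substream_seed(seed, "tc1")
    )
    paths["tc1"] = write_session(tc1_record, directory / "tc1.csv")

    # TC2 with the threshold appearing only after 8 steps of unaltered
    # workload: constructed log (ref step, then 8 constant-workload steps
    # whose slow drift only crosses the criterion at the eighth).
    workloads = [3.6, 3.8] + [3.9] * 8
    lactates = [2.30, 2.40, 2.60, 2.64, 2.67, 2.70, 2.73, 2.76, 2.79, 3.10]
    steps = _mk_steps(workloads, lactates)
    tc2_threshold = ThresholdResult(
        criterion="TC2", trigger_step=9, reference_step=1,
        delta_lactate=round(lactates[9] - lactates[1], 2),
        lt_workload=3.9, lt_lactate=lactates[9],
    )
    tc2_record = _constructed_record(
        "fixture-tc2-delayed", config, steps, tc2_threshold,
        estimate=3.8, outcome=COMPLETED, seed=seed,
    )
    paths["tc2_delayed"] = write_session(tc2_record, directory / "tc2_delayed.csv")

    # TC2a: slow creep over three consecutive constant-workload steps.
    workloads = [3.8, 3.8, 3.8, 3.8]
    lactates = [2.50, 2.62, 2.74, 2.87]
    steps = _mk_steps(workloads, lactates)
    tc2a_threshold = ThresholdResult(
        criterion="TC2a", trigger_step=3, reference_step=0,
        delta_lactate=round(lactates[3] - lactates[0], 2),
        lt_workload=3.8, lt_lactate=lactates[3],
    )
    tc2a_record = _constructed_record(
        "fixture-tc2a", config, steps, tc2a_threshold,
        estimate=3.7, outcome=COMPLETED, seed=seed,
    )
    paths["tc2a"] = write_session(tc2a_record, directory / "tc2a.csv")

    # Overshoot: the threshold-adaptation increment lands above this
    # subject's MLSS, gets corrected at the start of the test, and the
    # threshold is still detected afterwards.
    overshoot_record = run_ilt_test(
        _base_subject("fixture-overshoot", mlss_workload=3.55, supra_threshold_rate=6.0),
        config,
        seed=substream_seed(seed, "overshoot"),
    )
    paths["overshoot"] = write_session(overshoot_record, directory / "overshoot.csv")

    # Invalid: warm-up HR target unreachable.
    invalid_record = run_ilt_test(
        _base_subject("fixture-invalid", age=69.0, hr_rest=105.0),
        config,
        seed=substream_seed(seed, "invalid"),
    )
    paths["invalid"] = write_session(invalid_record, directory / "invalid.csv")
    return paths
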