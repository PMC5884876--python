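import pytest

from iltkit.controller import ProtocolConfig
from iltkit.criteria import Step
from iltkit.physiology import MeasurementModel, SubjectProfile


@pytest.fixture
def base_subject() -> SubjectProfile:
    return SubjectProfile(
        id="s-base",
        age=30.0,
        modality="running",
        mlss_workload=4.0,
        baseline_lactate=1.0,
        sub_threshold_gain=0.45,
        supra_threshold_rate=7.0,
        supra_onset_rise=0.40,
        lactate_time_constant=1.2,
        accumulation_lag_steps=0,
        hr_rest=60.0,
        hr_gain=28.0,
        hr_time_constant=0.7,
        rpe_at_mlss=5.0,
    )


@pytest.fixture
def noiseless_config() -> ProtocolConfig:
    return ProtocolConfig.default("running", measurement=MeasurementModel(cv=0.0))


@pytest.fixture
def noisy_config() -> ProtocolConfig:
    return ProtocolConfig.default("running")


def make_series(workloads, lactates, phase="fine_adaptation"):
    """Build a step series from parallel workload/lactate sequences."""
    return [
        Step(index=i, workload=w, duration=4.0, measured_lactate=l, phase=phase)
        for i, (w, l) in enumerate(zip(workloads, lactates))
    ]


@pytest.fixture
def series_builder():
    return make_series
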