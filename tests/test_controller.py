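import dataclasses

import numpy as np
import pytest

from iltkit._rng import stream
from iltkit.controller import (
    COMPLETED,
    CORRECTED_OVERSHOOT,
    INVALID,
    FtaDecision,
    ProtocolConfig,
    ProtocolError,
    handle_overshoot,
    next_workload_fta,
    run_ilt_test,
    run_warmup,
    threshold_adaptation,
)
from iltkit.criteria import TC1, TC2
from iltkit.physiology import MeasurementModel, make_cohort

from .conftest import make_series


class TestWarmup:
    def test_target_heart_rate_is_offset_minus_age(self, base_subject, noiseless_config):
        result = run_warmup(base_subject, noiseless_config, stream(0, "w"))
        # age 30 -> 140 bpm target; settled HR must sit in the band
        hr_at_settled = base_subject.hr_rest + base_subject.hr_gain * result.workload
        assert abs(hr_at_settled - 140.0) <= noiseless_config.warmup_settle_band + 1.0

    def test_settled_workload_inverts_hr_model(self, base_subject, noiseless_config):
        result = run_warmup(base_subject, noiseless_config, stream(0, "w"))
        expected = (140.0 - base_subject.hr_rest) / base_subject.hr_gain
        assert abs(result.workload - expected) <= noiseless_config.quantum

    def test_degenerate_age_rejected(self, base_subject, noiseless_config):
        ancient = dataclasses.replace(base_subject, age=170.0)
        with pytest.raises(ProtocolError):
            run_warmup(ancient, noiseless_config, stream(0, "w"))

    def test_unreachable_target_gives_invalid_session(self, base_subject, noiseless_config):
        ancient = dataclasses.replace(base_subject, age=170.0)
        record = run_ilt_test(ancient, noiseless_config, seed=0)
        assert record.outcome == INVALID
        assert record.mlss_workload_estimate is None


class TestThresholdAdaptation:
    def test_configured_mapping(self):
        config = ProtocolConfig.default("running", ta_slope=0.0, ta_intercept=0.4)
        assert threshold_adaptation(3.0, 1.5, config) == pytest.approx(3.4)

    def test_increment_floored_at_quantum(self):
        config = ProtocolConfig.default("running", ta_slope=0.0, ta_intercept=0.0)
        first = threshold_adaptation(3.0, 1.5, config)
        assert first == pytest.approx(3.0 + config.quantum)

    def test_first_workload_below_mlss_for_most_subjects(self, noiseless_config):
        cohort = make_cohort(100, "running", seed=3)
        below = 0
        for subject in cohort:
            warm = run_warmup(subject, noiseless_config, stream(0, "w", subject.id))
            first = threshold_adaptation(warm.workload, warm.lactate, noiseless_config)
            below += first < subject.mlss_workload
        assert below >= 80


class TestFtaDecision:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (0.10, FtaDecision("increase", 0.15, 0.10)),
            (0.19, FtaDecision("increase", 0.15, 0.19)),
            (0.20, FtaDecision("increase", 0.10, 0.20)),
            (0.30, FtaDecision("increase", 0.10, 0.30)),
            (0.40, FtaDecision("increase", 0.10, 0.40)),
            (0.41, FtaDecision("hold", 0.0, 0.41)),
        ],
    )
    def test_band_table(self, delta, expected):
        config = ProtocolConfig.default("running")
        steps = make_series([3.8, 3.8], [2.5, round(2.5 + delta, 2)])
        assert next_workload_fta(steps, config) == expected

    def test_first_post_ta_step_uses_lowest_band(self):
        config = ProtocolConfig.default("running")
        steps = make_series([3.8], [2.5])
        decision = next_workload_fta(steps, config)
        assert decision == FtaDecision("increase", 0.15, 0.0)

    def test_requires_history(self):
        with pytest.raises(ValueError):
            next_workload_fta([], ProtocolConfig.default("running"))


class TestOvershoot:
    def test_correction_size(self):
        config = ProtocolConfig.default("running")
        steps = make_series([3.0, 4.2], [2.0, 4.1])
        assert handle_overshoot(steps, config) == pytest.approx(4.0)

    def test_below_cutoff_no_handling(self, base_subject, noiseless_config):
        record = run_ilt_test(base_subject, noiseless_config, seed=1)
        assert record.outcome == COMPLETED  # never flagged corrected

    def test_corrected_session_recovers_truth(self, base_subject, noiseless_config):
        subject = dataclasses.replace(
            base_subject, mlss_workload=3.55, supra_threshold_rate=6.0
        )
        record = run_ilt_test(subject, noiseless_config, seed=2)
        assert record.outcome == CORRECTED_OVERSHOOT
        assert any("overshoot:correct" in s.decision for s in record.steps)
        error = abs(record.mlss_workload_estimate - subject.mlss_workload)
        assert error <= 0.15  # within one fine increment of truth


class TestVerification:
    def test_single_reduction_when_estimate_sub_threshold(
        self, base_subject, noiseless_config
    ):
        record = run_ilt_test(base_subject, noiseless_config, seed=1)
        verif = [s for s in record.steps if s.phase == "verification"]
        assert len(verif) == 1
        assert record.mlss_workload_estimate == pytest.approx(
            record.threshold.lt_workload - noiseless_config.verification_reduction
        )

    def test_second_reduction_when_first_still_supra(self, noiseless_config):
        # MLSS placed so the crossing overshoots by > one reduction
        subject = dataclasses.replace(
            make_cohort(1, "running", seed=0)[0],
            mlss_workload=3.62,
            accumulation_lag_steps=0,
        )
        record = run_ilt_test(subject, noiseless_config, seed=3)
        verif = [s for s in record.steps if s.phase == "verification"]
        if len(verif) == 2:
            assert "fail" in verif[0].decision and "pass" in verif[1].decision
            assert record.mlss_workload_estimate == pytest.approx(
                record.threshold.lt_workload
                - 2 * noiseless_config.verification_reduction
            )
        assert record.completed
        assert (
            subject.mlss_workload - 0.1
            < record.mlss_workload_estimate
            <= subject.mlss_workload
        )

    def test_noiseless_lag0_verification_first_try(self, base_subject, noiseless_config):
        record = run_ilt_test(base_subject, noiseless_config, seed=4)
        verif = [s for s in record.steps if s.phase == "verification"]
        assert record.outcome == COMPLETED and "pass" in verif[-1].decision


class TestRunIltTest:
    def test_noiseless_staircase_recovery(self, base_subject, noiseless_config):
        record = run_ilt_test(base_subject, noiseless_config, seed=0)
        assert record.outcome == COMPLETED
        assert 3.9 <= record.mlss_workload_estimate <= 4.0

    def test_lag_subject_fires_tc2(self, base_subject, noiseless_config):
        lagged = dataclasses.replace(base_subject, accumulation_lag_steps=3)
        record = run_ilt_test(lagged, noiseless_config, seed=0)
        assert record.threshold.criterion == TC2
        assert record.completed

    def test_lag0_subject_fires_tc1(self, base_subject, noiseless_config):
        record = run_ilt_test(base_subject, noiseless_config, seed=0)
        assert record.threshold.criterion == TC1

    def test_deterministic_under_seed(self, base_subject, noisy_config):
        a = run_ilt_test(base_subject, noisy_config, seed=11)
        b = run_ilt_test(base_subject, noisy_config, seed=11)
        assert a == b
        c = run_ilt_test(base_subject, noisy_config, seed=12)
        assert a != c

    def test_workloads_are_quantum_multiples(self, base_subject, noisy_config):
        record = run_ilt_test(base_subject, noisy_config, seed=5)
        q = noisy_config.quantum
        for step in record.steps:
            assert abs(step.workload / q - round(step.workload / q)) < 1e-6

    def test_single_increment_step_changes(self, base_subject, noisy_config):
        record = run_ilt_test(base_subject, noisy_config, seed=5)
        increments = {inc for _bound, inc in noisy_config.fta_table}
        protocol = [s for s in record.steps if s.phase == "fine_adaptation"]
        for prev, cur in zip(protocol, protocol[1:]):
            change = round(cur.workload - prev.workload, 6)
            if change > 0:
                assert change in {round(i, 6) for i in increments}

    def test_session_length_varies_across_subjects(self, noiseless_config):
        cohort = make_cohort(20, "running", seed=8)
        lengths = {len(run_ilt_test(s, noiseless_config, seed=0).steps) for s in cohort}
        assert len(lengths) > 1

    def test_phases_ordered(self, base_subject, noisy_config):
        record = run_ilt_test(base_subject, noisy_config, seed=5)
        order = {"warmup": 0, "adaptation": 1, "fine_adaptation": 2,
                 "verification": 3, "post": 4}
        ranks = [order[s.phase] for s in record.steps]
        assert ranks == sorted(ranks)

    def test_modality_mismatch_rejected(self, base_subject):
        with pytest.raises(ValueError):
            run_ilt_test(base_subject, ProtocolConfig.default("cycling"), seed=0)

    def test_max_steps_invariant_enforced(self):
        with pytest.raises(ValueError):
            ProtocolConfig.default("running", max_steps=5)

    def test_cycling_recovery(self):
        cohort = make_cohort(20, "cycling", seed=9)
        config = ProtocolConfig.default("cycling", measurement=MeasurementModel(cv=0.0))
        for subject in cohort:
            subject = dataclasses.replace(subject, accumulation_lag_steps=0)
            record = run_ilt_test(subject, config, seed=0)
            assert record.completed
            assert (
                subject.mlss_workload - 7.0
                < record.mlss_workload_estimate
                <= subject.mlss_workload
            )

    def test_exhaustion_extension_appends_post_steps(self, base_subject):
        config = ProtocolConfig.default(
            "running", measurement=MeasurementModel(cv=0.0), exhaustion_extension=True
        )
        record = run_ilt_test(base_subject, config, seed=0)
        post = [s for s in record.steps if s.phase == "post"]
        assert len(post) == 2
        plain = run_ilt_test(
            base_subject,
            ProtocolConfig.default("running", measurement=MeasurementModel(cv=0.0)),
            seed=0,
        )
        assert record.mlss_workload_estimate == plain.mlss_workload_estimate
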