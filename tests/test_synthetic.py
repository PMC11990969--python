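"""Generators: analytic ground truth, determinism, stability boundaries."""

import numpy as np
import pytest

from posturaltone.errors import ConfigurationError, InstabilityError, NoEventError
from posturaltone.events import detect_events
from posturaltone.signals import check_emg_quiescence
from posturaltone.synthetic import (
    CohortSpec,
    DynamoGroundTruth,
    PendulumGroundTruth,
    TaskGroundTruth,
    generate_cohort,
    generate_dynamometer_trial,
    generate_task_trial,
    simulate_quiet_standing,
)

from conftest import filtered


class TestDynamometer:
    def test_noiseless_linear_torque_exact(self):
        truth = DynamoGroundTruth(
            coeffs=(0, 0, 0, 0.4, 1.0), torque_noise_sd=0.0, emg_noise_sd=0.0, seed=0
        )
        trial = generate_dynamometer_trial(truth)
        assert np.allclose(trial.torque.values, 0.4 * trial.angle.values + 1.0, atol=1e-12)

    def test_angle_is_constant_velocity_ramp(self):
        trial = generate_dynamometer_trial(DynamoGroundTruth(seed=1))
        v = np.diff(trial.angle.values) * trial.angle.fs
        assert np.allclose(v, 5.0, atol=1e-9)
        assert trial.angle.values[0] == pytest.approx(-20.0)
        assert trial.angle.values[-1] == pytest.approx(15.0)

    def test_quiet_emg_envelopes_stay_below_gate(self):
        # resting noise of 1 uV must essentially never trip the 5 uV gate
        bad = sum(
            not check_emg_quiescence(
                generate_dynamometer_trial(DynamoGroundTruth(seed=s)).emg
            ).valid
            for s in range(300)
        )
        assert bad / 300 <= 0.01

    def test_contamination_burst_is_rejected_downstream(self):
        trial = generate_dynamometer_trial(
            DynamoGroundTruth(contamination=(2.0, 40.0), seed=3)
        )
        rep = check_emg_quiescence(trial.emg)
        assert not rep.valid
        assert rep.offending_channel == "SOL"
        assert rep.offending_time == pytest.approx(2.0, abs=0.1)

    def test_determinism(self):
        a = generate_dynamometer_trial(DynamoGroundTruth(seed=9))
        b = generate_dynamometer_trial(DynamoGroundTruth(seed=9))
        assert np.array_equal(a.torque.values, b.torque.values)
        assert all(
            np.array_equal(a.emg[m].values, b.emg[m].values) for m in ("TA", "SOL", "GM")
        )

    @pytest.mark.parametrize(
        "kw", [{"velocity": -1.0}, {"angle_range": (5.0, 15.0)}, {"fs": 0.0}]
    )
    def test_invalid_truth_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            DynamoGroundTruth(**kw)


class TestPendulum:
    def test_equilibrium_is_exactly_zero(self):
        rec = simulate_quiet_standing(
            PendulumGroundTruth(noise_torque_sd=0.0, theta0=0.0, seed=0)
        )
        assert np.all(rec.cop_ap.values == 0.0)
        assert np.all(rec.com_ap.values == 0.0)

    def test_instability_raises(self):
        truth = PendulumGroundTruth(K=600.0, seed=0)  # below mgh ~= 618
        with pytest.raises(InstabilityError):
            simulate_quiet_standing(truth)

    def test_undamped_oscillation_conserves_amplitude(self):
        rec = simulate_quiet_standing(
            PendulumGroundTruth(B=0.0, noise_torque_sd=0.0, theta0=0.01, seed=0)
        )
        com = rec.com_ap.values
        first = np.max(np.abs(com[: len(com) // 3]))
        last = np.max(np.abs(com[-len(com) // 3:]))
        assert abs(last - first) / first < 1e-4

    def test_cop_equals_moment_over_weight(self):
        truth = PendulumGroundTruth(seed=5)
        rec = simulate_quiet_standing(truth)
        # COP * mg must be a valid ankle moment: bounded by K * theta_max + B-term
        theta = np.arcsin(rec.com_ap.values / 1000.0 / truth.h)
        am = rec.cop_ap.values / 1000.0 * rec.body_weight
        resid = am - truth.K * theta
        assert np.abs(theta).max() < 0.05  # bounded sway
        assert np.abs(resid).mean() < np.abs(am).mean()  # damping term is small

    def test_sway_is_bounded_over_30s(self):
        for s in range(5):
            rec = simulate_quiet_standing(PendulumGroundTruth(seed=s))
            assert np.abs(rec.cop_ap.values).max() < 100.0  # mm


class TestTaskTrials:
    def test_null_amplitude_has_no_event(self, ):
        rec, _ = generate_task_trial(
            TaskGroundTruth(cop_step_amplitude=0.0, seed=4)
        )
        with pytest.raises(NoEventError):
            detect_events(filtered(rec), task="stand_to_sit")

    def test_excursion_reaches_programmed_amplitude(self):
        rec, _ = generate_task_trial(TaskGroundTruth(baseline_sd=0.0, seed=0))
        assert np.max(rec.cop_ap.values) == pytest.approx(20.0, rel=1e-6)

    def test_baseline_duration_always_present(self):
        with pytest.raises(ConfigurationError):
            TaskGroundTruth(onset_time=10.0, reversal_time=10.25)

    def test_ml_peak_window_invariant_enforced(self):
        with pytest.raises(ConfigurationError):
            TaskGroundTruth(task="gait_initiation", ml_peak_time=17.0)

    def test_emg_switches_at_onset(self):
        _, emg = generate_task_trial(TaskGroundTruth(seed=1))
        ta = emg.envelopes["DOM"]["TA"]
        i_pre = int(15.5 * ta.fs)
        i_post = int(17.0 * ta.fs)
        assert ta.values[i_pre] == pytest.approx(3.0)
        assert ta.values[i_post] == pytest.approx(15.0)

    def test_determinism(self):
        r1, e1 = generate_task_trial(TaskGroundTruth(seed=2))
        r2, e2 = generate_task_trial(TaskGroundTruth(seed=2))
        assert np.array_equal(r1.cop_ap.values, r2.cop_ap.values)
        assert np.array_equal(
            e1.envelopes["DOM"]["SOL"].values, e2.envelopes["DOM"]["SOL"].values
        )


class TestCohort:
    def test_reproducible_from_seed(self):
        spec = CohortSpec(n_per_group=3, seed=21)
        a = generate_cohort(spec, components=("dynamometer",))
        b = generate_cohort(spec, components=("dynamometer",))
        for da, db in zip(a, b):
            assert da.participant_id == db.participant_id
            for limb in da.limbs:
                for ta, tb in zip(da.dynamometer[limb], db.dynamometer[limb]):
                    assert np.array_equal(ta.torque.values, tb.torque.values)

    def test_layout_and_labels(self):
        cohort = generate_cohort(CohortSpec(n_per_group=3, seed=2), components=("dynamometer",))
        assert len(cohort) == 6
        healthy = [d for d in cohort if d.group == "healthy"]
        stroke = [d for d in cohort if d.group == "stroke"]
        assert healthy[0].limbs == ("DOM", "NDOM")
        assert stroke[0].limbs == ("IPSI", "CONTRA")
        assert all(len(d.dynamometer[limb]) == 3 for d in cohort for limb in d.limbs)

    def test_programmed_effect_shifts_contra_truth(self):
        null = generate_cohort(CohortSpec(n_per_group=3, seed=5), components=())
        eff = generate_cohort(
            CohortSpec(n_per_group=3, seed=5, effects={"contra_istiff_ratio": 2.0}),
            components=(),
        )
        for d_null, d_eff in zip(null, eff):
            if d_null.group == "stroke":
                ratio = (
                    d_eff.truth["stiff_scale"]["CONTRA"]
                    / d_null.truth["stiff_scale"]["CONTRA"]
                )
                assert ratio == pytest.approx(2.0)

    def test_unknown_effect_key_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(effects={"telekinesis": 2.0})

    def test_minimum_group_size(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_per_group=2)
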