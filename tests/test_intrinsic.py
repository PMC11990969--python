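"""Intrinsic stiffness: segmentation, gravity correction, quartic fit, pipeline."""

import numpy as np
import pytest

from posturaltone.errors import (
    DomainError,
    InsufficientDataError,
    SegmentationError,
    ValidityError,
)
from posturaltone.intrinsic import (
    DynamometerTrial,
    extract_df_segment,
    fit_torque_angle,
    gravity_correct,
    intrinsic_stiffness,
    stiffness_at,
)
from posturaltone.synthetic import DynamoGroundTruth, generate_dynamometer_trial

from conftest import make_signal

FS = 1000.0


def make_trial(angle, velocity=None, torque=None, emg_level=1.0):
    angle = np.asarray(angle, dtype=float)
    n = angle.size
    if velocity is None:
        velocity = np.gradient(angle) * FS
    if torque is None:
        torque = np.zeros(n)
    emg = {m: make_signal(np.full(n, emg_level), FS, label=m) for m in ("TA", "SOL", "GM")}
    return DynamometerTrial(
        angle=make_signal(angle, FS),
        torque=make_signal(torque, FS),
        velocity=make_signal(np.asarray(velocity, dtype=float), FS),
        emg=emg,
    )


class TestExtractSegment:
    def test_one_degree_trimmed_each_side(self):
        trial = generate_dynamometer_trial(
            DynamoGroundTruth(torque_noise_sd=0.0, emg_noise_sd=0.0, seed=0)
        )
        seg = extract_df_segment(trial)
        assert seg.angle.values[0] == pytest.approx(-19.0, abs=0.01)
        assert seg.angle.values[-1] == pytest.approx(14.0, abs=0.01)

    def test_velocity_spike_fails_validity(self):
        t = np.arange(0, 7, 1 / FS)
        angle = -20.0 + 5.0 * t
        velocity = np.full_like(angle, 5.0)
        velocity[3000:3050] = 8.0  # mid-sweep acceleration
        trial = make_trial(angle, velocity=velocity)
        with pytest.raises(ValidityError):
            extract_df_segment(trial)

    def test_pure_plantarflexion_has_no_segment(self):
        t = np.arange(0, 7, 1 / FS)
        trial = make_trial(15.0 - 5.0 * t)
        with pytest.raises(SegmentationError):
            extract_df_segment(trial)


class TestGravityCorrect:
    def test_zero_reference_is_identity(self):
        torque = make_signal(np.linspace(1, 5, 100), FS)
        angle = make_signal(np.linspace(-20, 15, 100), FS)
        out = gravity_correct(torque, angle, 0.0)
        assert np.array_equal(out.values, torque.values)

    @pytest.mark.parametrize("angle_deg,expected_drop", [(0.0, 2.0), (60.0, 1.0)])
    def test_cosine_scaling(self, angle_deg, expected_drop):
        torque = make_signal(np.full(100, 10.0), FS)
        angle = make_signal(np.full(100, angle_deg), FS)
        out = gravity_correct(torque, angle, 2.0)
        assert np.allclose(out.values, 10.0 - expected_drop)


class TestQuarticFit:
    def test_exact_recovery_noiseless(self):
        coeffs = (0.001, -0.002, 0.03, 0.4, 1.2)
        x = np.linspace(-19, 14, 3000)
        y = np.polyval(coeffs, x)
        model = fit_torque_angle(x, y)
        assert np.allclose(model.coeffs, coeffs, atol=1e-9)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_linear_data_gives_slope_only(self):
        x = np.linspace(-10, 10, 500)
        model = fit_torque_angle(x, 0.7 * x + 2.0)
        a, b, c, d, e = model.coeffs
        assert abs(a) < 1e-9 and abs(b) < 1e-9 and abs(c) < 1e-9
        assert d == pytest.approx(0.7, abs=1e-9)

    def test_noisy_fit_quality(self):
        # 1% noise on the torque range keeps r2 in the reported regime
        rng = np.random.default_rng(0)
        coeffs = (2e-5, 5e-4, 0.01, 0.42, 1.0)
        x = np.linspace(-19, 14, 3000)
        y0 = np.polyval(coeffs, x)
        noise_sd = 0.01 * np.ptp(y0)
        r2s = [
            fit_torque_angle(x, y0 + rng.normal(0, noise_sd, x.size)).r2
            for _ in range(100)
        ]
        assert min(r2s) > 0.99

    def test_narrow_span_rejected(self):
        x = np.linspace(0, 3, 100)
        with pytest.raises(ValidityError):
            fit_torque_angle(x, x**2)


class TestStiffnessAt:
    def test_derivative_at_zero_is_d(self):
        model = fit_torque_angle(np.linspace(-10, 10, 200), np.linspace(-10, 10, 200) * 0.5)
        assert stiffness_at(model, 0.0) == pytest.approx(0.5, abs=1e-9)

    def test_unit_coefficients(self):
        x = np.linspace(-5, 5, 500)
        y = x**4 + x**3 + x**2 + x + 1.0
        model = fit_torque_angle(x, y)
        assert stiffness_at(model, 1.0) == pytest.approx(10.0, rel=1e-6)

    def test_matches_finite_difference_everywhere(self):
        rng = np.random.default_rng(7)
        coeffs = rng.normal(0, 0.1, 5)
        x = np.linspace(-15, 12, 1000)
        model = fit_torque_angle(x, np.polyval(coeffs, x))
        h = 1e-5
        for xq in np.linspace(-14, 11, 23):
            fd = (model.torque(xq + h) - model.torque(xq - h)) / (2 * h)
            assert stiffness_at(model, xq) == pytest.approx(fd, abs=1e-6)

    def test_extrapolation_refused(self):
        model = fit_torque_angle(np.linspace(-10, 10, 200), np.linspace(-10, 10, 200))
        with pytest.raises(DomainError):
            stiffness_at(model, 25.0)


class TestIntrinsicStiffnessPipeline:
    def make_clean_trials(self, n=3, d=0.4):
        return [
            generate_dynamometer_trial(
                DynamoGroundTruth(
                    coeffs=(0, 0, 0, d, 1.0), torque_noise_sd=0.0, emg_noise_sd=0.0, seed=s
                )
            )
            for s in range(n)
        ]

    def test_noiseless_trials_recover_slope(self):
        res = intrinsic_stiffness(self.make_clean_trials())
        assert res.mean == pytest.approx(0.4, abs=1e-9)
        assert res.n_valid == 3
        assert all(r == pytest.approx(1.0, abs=1e-12) for r in res.r2_per_rep)

    def test_contaminated_trial_excluded_but_result_valid(self):
        bad = generate_dynamometer_trial(
            DynamoGroundTruth(contamination=(2.0, 40.0), torque_noise_sd=0.0, seed=9)
        )
        trials = [bad] + self.make_clean_trials()
        res = intrinsic_stiffness(trials)
        assert res.n_valid == 3
        assert res.mean == pytest.approx(0.4, abs=1e-9)

    def test_two_valid_trials_insufficient(self):
        with pytest.raises(InsufficientDataError) as err:
            intrinsic_stiffness(self.make_clean_trials(n=2))
        assert err.value.exclusions == []

    def test_exclusion_reasons_reported(self):
        bad = generate_dynamometer_trial(
            DynamoGroundTruth(contamination=(2.0, 40.0), torque_noise_sd=0.0, seed=9)
        )
        with pytest.raises(InsufficientDataError) as err:
            intrinsic_stiffness([bad] + self.make_clean_trials(n=2))
        assert any("5 uV" in reason for reason in err.value.exclusions)

    def test_parameter_recovery_under_noise(self):
        # torque noise at 1% of range: stiffness at 0 deg within 5% nearly always
        coeffs = (2e-5, 5e-4, 0.01, 0.42, 1.0)
        x = np.linspace(-20, 15, 100)
        noise_sd = 0.01 * np.ptp(np.polyval(coeffs, x))
        hits = 0
        n_trials = 60
        for s in range(n_trials):
            trial = generate_dynamometer_trial(
                DynamoGroundTruth(coeffs=coeffs, torque_noise_sd=noise_sd, seed=s)
            )
            seg = extract_df_segment(trial)
            model = fit_torque_angle(seg.angle.values, seg.torque.values)
            k = stiffness_at(model, 0.0)
            if abs(k - 0.42) / 0.42 < 0.05:
                hits += 1
        assert hits / n_trials >= 0.95

    def test_trimming_keeps_fit_stable_on_noiseless_data(self):
        # on noiseless repetitions the trimmed fits are all exact: the r2
        # spread across repetitions cannot exceed the untrimmed one
        trials = self.make_clean_trials()
        r2_trimmed, r2_full = [], []
        for tr in trials:
            seg = extract_df_segment(tr)
            r2_trimmed.append(fit_torque_angle(seg.angle.values, seg.torque.values).r2)
            r2_full.append(fit_torque_angle(tr.angle.values, tr.torque.values).r2)
        assert np.var(r2_trimmed) <= np.var(r2_full) + 1e-15
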