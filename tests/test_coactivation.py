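"""Antagonist coactivation: index identities, Table-style pair formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturaltone.coactivation import (
    EMGSet,
    coa_index,
    normalize_to_baseline,
    phase_rms,
    task_coactivation,
)
from posturaltone.errors import (
    ConfigurationError,
    NormalizationError,
    PosturalToneError,
    UndefinedIndexError,
)
from posturaltone.events import TaskEvents

from conftest import make_signal

FS = 1000.0


def emgset(levels: dict[str, float], sides=("DOM", "NDOM"), n=20_000, baseline=None):
    """Constant envelopes at the given phase levels, with an optional
    distinct level over the first 15 s baseline window."""
    envs = {}
    for side in sides:
        envs[side] = {}
        for muscle, level in levels.items():
            x = np.full(n, float(level))
            if baseline is not None:
                x[: int(15 * FS)] = baseline[muscle]
            envs[side][muscle] = make_signal(x, FS, label=muscle)
    return EMGSet(envelopes=envs)


EVENTS = TaskEvents(m0=16.0, m1=16.25, trigger_direction="AP")


class TestCoaIndex:
    def test_equal_activities_50(self):
        assert coa_index(1.0, 1.0) == 50.0

    def test_silent_antagonist_0(self):
        assert coa_index(0.0, 1.0) == 0.0

    def test_two_to_one(self):
        assert coa_index(2.0, 1.0) == pytest.approx(66.667, abs=1e-3)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedIndexError):
            coa_index(0.0, 0.0)

    @given(
        a=st.floats(min_value=1e-6, max_value=1e6),
        b=st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_complement_identity_and_bounds(self, a, b):
        c1, c2 = coa_index(a, b), coa_index(b, a)
        assert c1 + c2 == pytest.approx(100.0, abs=1e-9)
        assert 0.0 <= c1 <= 100.0

    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=1e-3, max_value=1e3),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, a, b, scale):
        assert coa_index(a * scale, b * scale) == pytest.approx(coa_index(a, b), rel=1e-9)


class TestNormalizeAndPhaseRms:
    def test_baseline_level_becomes_unity(self):
        env = make_signal(np.full(20_000, 2.0), FS)
        out = normalize_to_baseline(env, (0.0, 15.0))
        assert np.allclose(out.values, 1.0)

    def test_phase_level_scaled_by_baseline(self):
        x = np.full(20_000, 6.0)
        x[: 15_000] = 2.0
        out = normalize_to_baseline(make_signal(x, FS), (0.0, 15.0))
        assert out.values[-1] == pytest.approx(3.0)

    def test_zero_baseline_rejected(self):
        x = np.zeros(20_000)
        x[16_000:] = 5.0
        with pytest.raises(NormalizationError):
            normalize_to_baseline(make_signal(x, FS), (0.0, 15.0))

    def test_constant_phase_rms(self):
        env = make_signal(np.full(20_000, 3.0), FS)
        assert phase_rms(env, EVENTS) == pytest.approx(3.0)

    def test_ramp_phase_rms_closed_form(self):
        # RMS of a 0..1 ramp is sqrt(integral of x^2) = sqrt(1/3)
        x = np.zeros(20_000)
        i0, i1 = 16_000, 16_250
        x[i0:i1] = np.linspace(0.0, 1.0, i1 - i0)
        assert phase_rms(make_signal(x, FS), EVENTS) == pytest.approx(np.sqrt(1 / 3), abs=2e-3)

    def test_empty_interval_rejected(self):
        env = make_signal(np.ones(20_000), FS)
        with pytest.raises(PosturalToneError):
            phase_rms(env, TaskEvents(m0=16.0, m1=16.0005, trigger_direction="AP"))


class TestTaskCoactivation:
    def test_standing_pairs_and_values(self):
        # raw standing activities: TA 2, SOL 1, GM 1
        emg = emgset({"TA": 2.0, "SOL": 1.0, "GM": 1.0}, n=30_000)
        res = {r.pair: r.coa for r in task_coactivation(emg, None, "standing") if r.side == "DOM"}
        assert res["TA/SOL"] == pytest.approx(100 * 2 / 3)
        assert res["TA/GM"] == pytest.approx(100 * 2 / 3)
        assert res["Ve/Do"] == pytest.approx(50.0)  # 2 / (1 + 1 + 2)

    def test_transition_pairs_and_values(self):
        # baseline 1 uV everywhere; phase TA 2, SOL 1, GM 1
        emg = emgset(
            {"TA": 2.0, "SOL": 1.0, "GM": 1.0},
            baseline={"TA": 1.0, "SOL": 1.0, "GM": 1.0},
        )
        res = {r.pair: r.coa for r in task_coactivation(emg, EVENTS, "stand_to_sit") if r.side == "DOM"}
        assert res["SOL/TA"] == pytest.approx(100 / 3, abs=1e-6)
        assert res["GM/TA"] == pytest.approx(100 / 3, abs=1e-6)
        assert res["Do/Ve"] == pytest.approx(50.0, abs=1e-6)  # (1+1) / (2 + 1+1)

    def test_balanced_pairs_give_50(self):
        # every pair's antagonist equals its agonist (TA = SOL + GM)
        emg_standing = emgset({"TA": 1.0, "SOL": 1.0, "GM": 1.0}, n=30_000)
        standing = {r.pair: r.coa for r in task_coactivation(emg_standing, None, "standing")}
        assert standing["TA/SOL"] == pytest.approx(50.0)
        assert standing["TA/GM"] == pytest.approx(50.0)
        emg_tr = emgset(
            {"TA": 2.0, "SOL": 1.0, "GM": 1.0},
            baseline={"TA": 1.0, "SOL": 1.0, "GM": 1.0},
        )
        trans = {r.pair: r.coa for r in task_coactivation(emg_tr, EVENTS, "gait_initiation")}
        assert trans["Do/Ve"] == pytest.approx(50.0, abs=1e-6)

    def test_printed_dove_denominator_variant(self):
        emg = emgset(
            {"TA": 2.0, "SOL": 1.0, "GM": 1.0},
            baseline={"TA": 1.0, "SOL": 1.0, "GM": 1.0},
        )
        res = {
            r.pair: r.coa
            for r in task_coactivation(emg, EVENTS, "stand_to_sit", printed_dove_denominator=True)
        }
        # denominator as printed: (SOL + TA) + (SOL + GM) = 3 + 2
        assert res["Do/Ve"] == pytest.approx(100 * 2 / 5, abs=1e-6)

    def test_common_rescaling_leaves_indices_unchanged(self):
        emg1 = emgset({"TA": 2.0, "SOL": 1.5, "GM": 0.5},
                      baseline={"TA": 1.0, "SOL": 1.0, "GM": 1.0})
        emg2 = emgset({"TA": 8.0, "SOL": 6.0, "GM": 2.0},
                      baseline={"TA": 4.0, "SOL": 4.0, "GM": 4.0})
        r1 = {r.pair: r.coa for r in task_coactivation(emg1, EVENTS, "stand_to_sit")}
        r2 = {r.pair: r.coa for r in task_coactivation(emg2, EVENTS, "stand_to_sit")}
        for pair in r1:
            assert r1[pair] == pytest.approx(r2[pair], rel=1e-9)

    def test_bounds_on_random_activity_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = rng.uniform(1e-3, 100, 2)
            assert 0.0 <= coa_index(a, b) <= 100.0

    def test_missing_channel_rejected(self):
        emg = emgset({"TA": 1.0, "SOL": 1.0}, n=30_000)
        with pytest.raises(ConfigurationError):
            task_coactivation(emg, None, "standing")

    def test_transitions_require_events(self):
        emg = emgset({"TA": 1.0, "SOL": 1.0, "GM": 1.0})
        with pytest.raises(ConfigurationError):
            task_coactivation(emg, None, "stand_to_sit")
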