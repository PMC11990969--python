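"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from posturaltone import StanceRecording, TaskGroundTruth, generate_task_trial
from posturaltone.signals import SampledSignal, lowpass_cop


def filtered(rec: StanceRecording) -> StanceRecording:
    """Standard COP conditioning applied to a stance recording."""
    return StanceRecording(
        cop_ap=lowpass_cop(rec.cop_ap),
        cop_ml=lowpass_cop(rec.cop_ml),
        fz=rec.fz,
        com_ap=rec.com_ap,
        body_weight=rec.body_weight,
        h=rec.h,
        task=rec.task,
    )


def brute_force_sampen(x: np.ndarray, m: int, r: float) -> float:
    """Literal template-pair counting definition of sample entropy."""
    n = len(x)
    def count(k: int) -> int:
        total = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + d] - x[j + d]) for d in range(k)) <= r:
                    total += 1
        return total
    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def brute_force_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Literal centred-window RMS with edge truncation."""
    n = len(x)
    half_lo = window // 2
    half_hi = window - half_lo
    out = np.empty(n)
    for i in range(n):
        seg = x[max(0, i - half_lo): min(n, i + half_hi)]
        out[i] = np.sqrt(np.mean(seg**2))
    return out


@pytest.fixture(scope="session")
def logistic_series() -> np.ndarray:
    """Fully chaotic logistic-map orbit (r = 4), 5000 points."""
    x = np.empty(5000)
    x[0] = 0.2
    for i in range(1, x.size):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x


@pytest.fixture(scope="session")
def sts_trial():
    """One default stand-to-sit trial (onset 16 s, reversal 16.25 s)."""
    return generate_task_trial(TaskGroundTruth(task="stand_to_sit", seed=11))


def make_signal(values, fs=1000.0, **kw) -> SampledSignal:
    return SampledSignal(np.asarray(values, dtype=float), fs, **kw)
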