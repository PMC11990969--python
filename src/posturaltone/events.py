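"""Postural-phase landmark detection from COP traces.

The postural (anticipatory) phase of a transition task is bounded by:

* ``T0`` — gait initiation only: the first local extremum of the COP-ML
  trace whose deviation from the baseline mean exceeds 3 baseline SDs.
* ``M0`` — phase onset: the earliest instant, searched within
  [T0 - 450 ms, T0 + 50 ms] when T0 exists (from the end of the baseline
  window otherwise), from which |COP - baseline mean| stays above 3 SD for
  at least 50 ms consecutively, in either the AP or ML direction; the
  earlier direction wins.
* ``M1`` — phase end: the first instant after M0 at which the triggering
  channel's curve inverts (slope sign change on a 20 ms-smoothed
  derivative, so noise-driven micro-inversions do not qualify).

Baseline statistics come from a 15 s quiet-standing window preceding the
task.  Detection is translation-invariant: only deviations from the
baseline mean matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoEventError, SignalLengthError
from .signals import SampledSignal

from .functional import StanceRecording

__all__ = [
    "BaselineStats",
    "TaskEvents",
    "compute_baseline",
    "detect_t0",
    "detect_m0",
    "detect_m1",
    "detect_events",
]

BASELINE_WINDOW_S = 15.0
SD_MULTIPLIER = 3.0
PERSISTENCE_S = 0.050
T0_WINDOW_BEFORE_S = 0.450
T0_WINDOW_AFTER_S = 0.050
SLOPE_SMOOTH_S = 0.020


@dataclass(frozen=True)
class BaselineStats:
    """Per-direction COP mean and SD over the quiet-standing baseline window."""

    mean_ap: float
    sd_ap: float
    mean_ml: float
    sd_ml: float
    window: tuple[float, float]


@dataclass(frozen=True)
class TaskEvents:
    """Detected landmarks of one task trial (times in s from record start)."""

    m0: float
    m1: float
    trigger_direction: str  # "AP" or "ML"
    t0: float | None = None

    def __post_init__(self):
        if not self.m0 < self.m1:
            raise ValueError(f"m0 ({self.m0}) must precede m1 ({self.m1})")


def compute_baseline(
    rec: "StanceRecording", window: tuple[float, float] | None = None
) -> BaselineStats:
    """Mean and SD of COP-AP / COP-ML over a 15 s quiet-standing window.

    ``window`` defaults to the first 15 s of the record.
    """
    if window is None:
        window = (0.0, BASELINE_WINDOW_S)
    start, end = window
    if end - start < BASELINE_WINDOW_S - 0.5 / rec.fs:
        raise SignalLengthError(
            f"baseline window of {end - start:.2f} s shorter than {BASELINE_WINDOW_S} s"
        )
    if rec.cop_ap.duration < end:
        raise SignalLengthError(
            f"record of {rec.cop_ap.duration:.2f} s does not contain baseline window ending at {end} s"
        )
    ap = rec.cop_ap.slice_time(start, end).values
    ml = rec.cop_ml.slice_time(start, end).values
    return BaselineStats(
        mean_ap=float(ap.mean()),
        sd_ap=float(ap.std()),
        mean_ml=float(ml.mean()),
        sd_ml=float(ml.std()),
        window=(float(start), float(end)),
    )


def _smoothed_slope(values: np.ndarray, fs: float, smooth_s: float = SLOPE_SMOOTH_S) -> np.ndarray:
    # centred moving average with truncated (not zero-padded) edges, so the
    # record boundaries cannot fabricate slope inversions
    win = max(int(round(smooth_s * fs)), 1)
    n = values.size
    cs = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.clip(idx - win // 2, 0, n)
    hi = np.clip(idx + win - win // 2, 0, n)
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return np.gradient(smoothed) * fs


def detect_t0(cop_ml: SampledSignal, baseline: BaselineStats) -> float:
    """First supra-threshold local extremum of the COP-ML trace.

    A qualifying extremum is a local maximum of |COP_ML - baseline mean|
    exceeding 3 * sd_ml, searched from the end of the baseline window.  To
    distinguish a displacement peak from an isolated noise spike, the
    supra-threshold episode containing the extremum must persist for at
    least 50 ms (the same persistence the M0 rule uses).
    """
    fs = cop_ml.fs
    start_idx = int(round(baseline.window[1] * fs))
    dev = np.abs(cop_ml.values - baseline.mean_ml)
    thr = SD_MULTIPLIER * baseline.sd_ml
    onset = _first_persistent_onset(dev, thr, fs, start_idx, dev.size, PERSISTENCE_S)
    if onset is None:
        raise NoEventError("no persistent supra-threshold COP-ML displacement found (T0)")
    slope = _smoothed_slope(cop_ml.values - baseline.mean_ml, fs)
    sign = np.sign(slope)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0) + 1
    for i in flips:
        if i >= onset and dev[i] > thr:
            return i / fs
    raise NoEventError("no supra-threshold COP-ML extremum found (T0)")


def _first_persistent_onset(
    dev: np.ndarray, thr: float, fs: float, lo: int, hi: int, persistence_s: float
) -> int | None:
    """Earliest index in [lo, hi) from which dev > thr holds for >= persistence_s."""
    need = max(int(round(persistence_s * fs)), 1)
    above = dev > thr
    if not above[lo:hi].any():
        return None
    # run lengths of consecutive True starting at each index
    run = np.zeros(above.size + 1, dtype=int)
    for i in range(above.size - 1, -1, -1):
        run[i] = run[i + 1] + 1 if above[i] else 0
    for i in range(lo, min(hi, above.size)):
        if above[i] and run[i] >= need:
            return i
    return None


def detect_m0(
    rec: "StanceRecording",
    baseline: BaselineStats,
    t0: float | None = None,
    persistence_s: float = PERSISTENCE_S,
) -> tuple[float, str]:
    """Postural-phase onset: earliest persistent 3 SD deviation in AP or ML.

    Returns ``(time_s, direction)`` with direction ``"AP"`` or ``"ML"``.
    """
    fs = rec.fs
    n = len(rec.cop_ap)
    if t0 is not None:
        lo = max(int(round((t0 - T0_WINDOW_BEFORE_S) * fs)), 0)
        hi = min(int(round((t0 + T0_WINDOW_AFTER_S) * fs)) + 1, n)
    else:
        lo = int(round(baseline.window[1] * fs))
        hi = n
    candidates: list[tuple[int, str]] = []
    for direction, sig, mean, sd in (
        ("AP", rec.cop_ap, baseline.mean_ap, baseline.sd_ap),
        ("ML", rec.cop_ml, baseline.mean_ml, baseline.sd_ml),
    ):
        dev = np.abs(sig.values - mean)
        idx = _first_persistent_onset(dev, SD_MULTIPLIER * sd, fs, lo, hi, persistence_s)
        if idx is not None:
            candidates.append((idx, direction))
    if not candidates:
        raise NoEventError(
            "no persistent supra-threshold COP deviation found in the M0 search window"
        )
    idx, direction = min(candidates)
    return idx / fs, direction


def detect_m1(cop_channel: SampledSignal, m0: float) -> float:
    """Phase end: first slope-sign inversion of the triggering channel after M0."""
    fs = cop_channel.fs
    i0 = int(round(m0 * fs))
    if i0 >= len(cop_channel) - 2:
        raise NoEventError("record does not extend beyond M0")
    slope = _smoothed_slope(cop_channel.values, fs)
    after = slope[i0:]
    ref = np.sign(after[np.flatnonzero(after)[0]]) if np.flatnonzero(after).size else 0.0
    if ref == 0.0:
        raise NoEventError("flat signal after M0; no curve inversion")
    flips = np.flatnonzero(np.sign(after) == -ref)
    if flips.size == 0:
        raise NoEventError("signal monotone to end of record; no curve inversion (M1)")
    return (i0 + flips[0]) / fs


def detect_events(
    rec: "StanceRecording",
    baseline: BaselineStats | None = None,
    task: str = "stand_to_sit",
) -> TaskEvents:
    """Full landmark detection for one transition trial.

    For gait initiation T0 is located first and constrains the M0 search
    window; for stand-to-sit the same M0/M1 criteria run without T0.
    """
    if baseline is None:
        baseline = compute_baseline(rec)
    t0 = detect_t0(rec.cop_ml, baseline) if task == "gait_initiation" else None
    m0, direction = detect_m0(rec, baseline, t0=t0)
    channel = rec.cop_ap if direction == "AP" else rec.cop_ml
    m1 = detect_m1(channel, m0)
    return TaskEvents(m0=m0, m1=m1, trigger_direction=direction, t0=t0)
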